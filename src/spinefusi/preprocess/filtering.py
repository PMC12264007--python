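"""Zero-delay lowpass filtering of slow hemodynamic signals.

A Kaiser-window FIR lowpass is designed for a passband edge of 0.04 Hz
and a stopband edge at twice the passband (at the 1 Hz frame rate), with
at least 60 dB stopband attenuation; forward-backward application
cancels the group delay exactly and squares the attenuation.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

__all__ = ["design_lowpass", "lowpass_filter", "lowpass_stack"]


def design_lowpass(
    passband_hz: float = 0.04,
    stopband_atten_db: float = 60.0,
    fs: float = 1.0,
) -> np.ndarray:
    """FIR taps meeting the passband/attenuation contract.

    The transition band spans ``passband_hz`` to ``2 * passband_hz``;
    the -6 dB cutoff sits at the band center.  DC gain is exactly one.
    """
    if not 0 < passband_hz < fs / 2:
        raise ValueError("passband must lie in (0, Nyquist)")
    if stopband_atten_db <= 0:
        raise ValueError("stopband attenuation must be positive")
    width = passband_hz  # transition width in Hz
    numtaps, beta = signal.kaiserord(stopband_atten_db, width / (0.5 * fs))
    numtaps |= 1  # odd length -> integer group delay, symmetric
    cutoff = passband_hz + width / 2.0
    return signal.firwin(numtaps, cutoff, window=("kaiser", beta), fs=fs)


def lowpass_filter(
    series: np.ndarray,
    passband_hz: float = 0.04,
    stopband_atten_db: float = 60.0,
    fs: float = 1.0,
    axis: int = -1,
) -> np.ndarray:
    """Delay-compensated lowpass along ``axis``.

    Raises when the series is shorter than the filter warm-up (its
    length must exceed the filter order).
    """
    taps = design_lowpass(passband_hz, stopband_atten_db, fs)
    x = np.asarray(series, dtype=float)
    n = x.shape[axis]
    if n <= taps.size:
        raise ValueError(
            f"series length {n} must exceed the filter order ({taps.size - 1})"
        )
    padlen = min(3 * taps.size, n - 1)
    return signal.filtfilt(taps, [1.0], x, axis=axis, padlen=padlen)


def lowpass_stack(stack, passband_hz: float = 0.04, stopband_atten_db: float = 60.0):
    """Lowpass every pixel time series of a :class:`PDStack`."""
    filtered = lowpass_filter(
        stack.data, passband_hz, stopband_atten_db, fs=stack.frame_rate_hz, axis=-1
    )
    return stack.copy_with(filtered)
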