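"""Rigid frame registration by sub-pixel phase correlation.

The cross-power spectrum of reference and frame is normalized with a
small additive regularizer (a fraction of the peak cross-spectral
magnitude); full whitening is numerically fragile for smooth, low-contrast
images.  The correlation peak is refined to sub-pixel precision with
separable three-point quadratic fits along each axis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..synthetic_data.phantom import PDStack

__all__ = ["MotionEstimate", "estimate_motion", "correct_motion", "phase_correlate"]

logger = logging.getLogger(__name__)

#: Regularizer for the cross-power normalization, relative to the peak magnitude.
_SPECTRUM_EPS = 0.01


@dataclass
class MotionEstimate:
    """Per-frame rigid translation relative to a reference image.

    ``shifts[i]`` is the (row, col) displacement that maps the reference
    onto frame ``i`` (same convention as motion injection), in pixels.
    """

    shifts: np.ndarray
    peak_correlation: np.ndarray
    reference_id: str
    max_shift_px: float = 10.0

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 2:
            raise ValueError("shifts must have shape (n_frames, 2)")
        if not np.all(np.isfinite(self.shifts)):
            raise ValueError("shifts must be finite")

    @property
    def n_frames(self) -> int:
        return self.shifts.shape[0]


def _quadratic_offset(cm1: float, c0: float, cp1: float) -> float:
    denom = cm1 - 2.0 * c0 + cp1
    if denom == 0.0:
        return 0.0
    off = 0.5 * (cm1 - cp1) / denom
    return float(np.clip(off, -0.5, 0.5))


def phase_correlate(reference: np.ndarray, frame: np.ndarray) -> tuple[np.ndarray, float]:
    """Estimate the (row, col) shift mapping ``reference`` onto ``frame``.

    Returns the sub-pixel shift and the correlation peak height (clipped
    to [0, 1]).  Raises on a zero frame or reference, whose spectrum
    carries no phase information.
    """
    ref = np.asarray(reference, dtype=float)
    mov = np.asarray(frame, dtype=float)
    if ref.shape != mov.shape:
        raise ValueError("reference and frame shapes differ")
    if not np.any(ref) or not np.any(mov):
        raise ValueError("all-zero image: phase spectrum undefined")

    f_ref = np.fft.fft2(ref)
    f_mov = np.fft.fft2(mov)
    cross = f_ref * np.conj(f_mov)
    mag = np.abs(cross)
    weight = mag / (mag + _SPECTRUM_EPS * mag.max())
    corr = np.real(np.fft.ifft2(cross / (mag + _SPECTRUM_EPS * mag.max())))
    corr /= max(weight.mean(), 1e-30)  # peak == 1 for identical images

    n0, n1 = corr.shape
    pr, pc = np.unravel_index(int(np.argmax(corr)), corr.shape)
    dr = _quadratic_offset(corr[(pr - 1) % n0, pc], corr[pr, pc], corr[(pr + 1) % n0, pc])
    dc = _quadratic_offset(corr[pr, (pc - 1) % n1], corr[pr, pc], corr[pr, (pc + 1) % n1])
    sr = pr + dr
    sc = pc + dc
    if sr > n0 / 2:
        sr -= n0
    if sc > n1 / 2:
        sc -= n1
    peak = float(np.clip(corr[pr, pc], 0.0, 1.0))
    # corr peaks at minus the reference->frame displacement
    return np.array([-sr, -sc]), peak


def estimate_motion(
    stack: PDStack,
    reference: str = "baseline_mean",
    max_shift_px: float = 10.0,
) -> MotionEstimate:
    """Per-frame translation estimates against a fixed reference.

    ``reference`` is ``"baseline_mean"`` (mean of the baseline window;
    falls back to the global mean when the stack has no baseline frames)
    or ``"first_frame"``.
    """
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if reference == "baseline_mean":
        nb = stack.baseline_frames if stack.baseline_frames >= 1 else stack.n_frames
        ref = stack.data[:, :, :nb].mean(axis=2)
    elif reference == "first_frame":
        ref = stack.data[:, :, 0]
    else:
        raise ValueError(f"unknown reference {reference!r}")

    shifts = np.empty((stack.n_frames, 2))
    peaks = np.empty(stack.n_frames)
    for i in range(stack.n_frames):
        shifts[i], peaks[i] = phase_correlate(ref, stack.data[:, :, i])
    return MotionEstimate(
        shifts=shifts,
        peak_correlation=peaks,
        reference_id=reference,
        max_shift_px=max_shift_px,
    )


def correct_motion(stack: PDStack, motion: MotionEstimate, order: int = 3) -> PDStack:
    """Translate each frame by the negated estimated shift.

    Shifts beyond ``motion.max_shift_px`` are clamped with a warning.
    Uses the same spline interpolation family (constant-edge padding) as
    motion injection.
    """
    if motion.n_frames != stack.n_frames:
        raise ValueError("motion estimate does not match frame count")
    shifts = motion.shifts.copy()
    excess = np.abs(shifts) > motion.max_shift_px
    if np.any(excess):
        warnings.warn(
            f"{int(np.any(excess, axis=1).sum())} frame shift(s) exceed "
            f"{motion.max_shift_px} px; clamped",
            stacklevel=2,
        )
        logger.warning("clamping %d out-of-range shifts", int(excess.sum()))
        shifts = np.clip(shifts, -motion.max_shift_px, motion.max_shift_px)

    out = np.empty_like(stack.data)
    for i in range(stack.n_frames):
        if shifts[i, 0] == 0.0 and shifts[i, 1] == 0.0:
            out[:, :, i] = stack.data[:, :, i]
        else:
            out[:, :, i] = ndimage.shift(
                stack.data[:, :, i], -shifts[i], order=order, mode="nearest"
            )
    return stack.copy_with(out)
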