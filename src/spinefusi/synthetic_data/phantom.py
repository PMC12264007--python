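"""Power-Doppler phantom stacks with planted pressure-coupled regions."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .pressure import BladderTrace, percent_bp
from .protocol import ProtocolSpec

__all__ = [
    "PDStack",
    "PhantomTruth",
    "PhantomConfig",
    "make_hrf_kernel",
    "generate_phantom",
    "inject_motion",
]


@dataclass
class PDStack:
    """Power-Doppler image time series.

    ``data`` has shape (depth_px, width_px, frames); depth grows downward
    to mirror the ultrasound display.  Default geometry is 91 x 128 px at
    0.1 mm pitch (9.1 mm x 12.8 mm field of view) sampled at 1 Hz with a
    300-frame baseline window.
    """

    data: np.ndarray
    pixel_pitch_mm: float = 0.1
    frame_rate_hz: float = 1.0
    baseline_frames: int = 300
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("PDStack data must be 3D (depth, width, frames)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("PDStack data must be finite")
        if not 0 <= self.baseline_frames <= self.n_frames:
            raise ValueError("baseline_frames out of range")

    @property
    def shape_px(self) -> tuple[int, int]:
        return self.data.shape[0], self.data.shape[1]

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    @property
    def fov_mm(self) -> tuple[float, float]:
        return (
            self.data.shape[0] * self.pixel_pitch_mm,
            self.data.shape[1] * self.pixel_pitch_mm,
        )

    def copy_with(self, data: np.ndarray) -> "PDStack":
        return PDStack(
            data=data,
            pixel_pitch_mm=self.pixel_pitch_mm,
            frame_rate_hz=self.frame_rate_hz,
            baseline_frames=self.baseline_frames,
            metadata=dict(self.metadata),
        )


@dataclass
class PhantomTruth:
    """Ground truth for parameter-recovery tests.

    Masks are disjoint; ``gains`` is zero outside the responsive masks;
    ``hrf_kernel`` is nonnegative with unit sum; ``motion_truth`` is the
    per-frame (row, col) shift in pixels (zeros until motion is injected).
    """

    pos_mask: np.ndarray
    neg_mask: np.ndarray
    null_mask: np.ndarray
    gains: np.ndarray
    hrf_kernel: np.ndarray
    noise_sd: float
    drift_params: dict
    motion_truth: np.ndarray
    seed: int
    baseline_map: np.ndarray | None = None
    bp_norm: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.pos_mask & self.neg_mask):
            raise ValueError("pos_mask and neg_mask overlap")
        if np.any(self.null_mask & (self.pos_mask | self.neg_mask)):
            raise ValueError("null_mask overlaps a responsive mask")
        if not np.isclose(self.hrf_kernel.sum(), 1.0):
            raise ValueError("hrf_kernel must sum to 1")
        if np.any(self.hrf_kernel < 0):
            raise ValueError("hrf_kernel must be nonnegative")
        if np.any(self.gains[self.null_mask] != 0):
            raise ValueError("gains must be zero on null_mask")


@dataclass(frozen=True)
class PhantomConfig:
    """Configuration of the planted-region phantom.

    ``region_fraction`` sizes each responsive region as a fraction of the
    pixel grid (matched to the downstream top-fraction mask rule, ceil
    rounding).  Noise is multiplicative (speckle-like, proportional to the
    pixel baseline) and stated in percent-of-baseline units: either
    ``noise_sd`` directly, or ``noise_snr`` = temporal SD of the weaker
    planted percent signal divided by the percent noise SD.
    """

    shape: tuple[int, int] = (91, 128)
    gain_pos: float = 120.0
    gain_neg: float = -45.0
    region_fraction: float = 0.05
    hrf_time_to_peak_s: float = 3.0
    hrf_length_s: float = 15.0
    identity_kernel: bool = False
    noise_sd: float | None = None
    noise_snr: float | None = 2.0
    drift_amplitude: float = 0.0
    drift_freqs_hz: tuple[float, ...] = (0.004, 0.007)
    baseline_background: float = 50.0
    vessel_amplitude: float = 400.0

    def __post_init__(self) -> None:
        if not (0 < self.region_fraction <= 0.5):
            raise ValueError("region_fraction must be in (0, 0.5]")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_snr is not None and self.noise_snr <= 0:
            raise ValueError("noise_snr must be > 0")


def make_hrf_kernel(time_to_peak_s: float = 3.0, length_s: float = 15.0, fs: float = 1.0) -> np.ndarray:
    """Gamma-shaped nonnegative kernel with unit sum.

    Shape parameter chosen so the mode sits at ``time_to_peak_s``.
    """
    t = np.arange(0.0, length_s, 1.0 / fs)
    shape = 3.0
    scale = time_to_peak_s / (shape - 1.0)
    k = t ** (shape - 1.0) * np.exp(-t / scale)
    s = k.sum()
    if s <= 0:
        raise ValueError("degenerate kernel")
    return k / s


def _baseline_map(shape: tuple[int, int], cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Bright curvilinear vessel structures over a dim smooth background."""
    d, w = shape
    bg = rng.standard_normal((d, w))
    bg = ndimage.gaussian_filter(bg, sigma=max(d, w) / 10.0)
    bg = cfg.baseline_background * (1.0 + 0.3 * bg / max(np.abs(bg).max(), 1e-12))

    vessels = np.zeros((d, w))
    cols = np.arange(w)
    n_vessels = 4
    for _ in range(n_vessels):
        r0 = rng.uniform(0.15, 0.85) * d
        amp = rng.uniform(0.05, 0.2) * d
        freq = rng.uniform(0.5, 2.0)
        phase = rng.uniform(0, 2 * np.pi)
        rows = r0 + amp * np.sin(2 * np.pi * freq * cols / w + phase)
        ridx = np.clip(np.round(rows).astype(int), 0, d - 1)
        vessels[ridx, cols] += rng.uniform(0.5, 1.0)
    vessels = ndimage.gaussian_filter(vessels, sigma=1.2)
    vmax = vessels.max()
    if vmax > 0:
        vessels = cfg.vessel_amplitude * vessels / vmax
    return bg + vessels


def _sized_disk_mask(shape: tuple[int, int], center: tuple[float, float], n_px: int) -> np.ndarray:
    """Boolean mask of exactly ``n_px`` pixels nearest to ``center``."""
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    dist = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    flat = np.argsort(dist, axis=None, kind="stable")[:n_px]
    mask = np.zeros(shape, dtype=bool)
    mask.flat[flat] = True
    return mask


def default_truth_masks(shape: tuple[int, int], fraction: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint positive/negative disks, each exactly ceil(fraction * npix)."""
    n_px = int(np.ceil(fraction * shape[0] * shape[1]))
    pos = _sized_disk_mask(shape, (shape[0] * 0.35, shape[1] * 0.3), n_px)
    neg = _sized_disk_mask(shape, (shape[0] * 0.6, shape[1] * 0.72), n_px)
    if np.any(pos & neg):
        raise ValueError("region_fraction too large: planted regions overlap")
    return pos, neg


def generate_phantom(
    config: PhantomConfig,
    bp: BladderTrace,
    protocol: ProtocolSpec,
    seed: int = 0,
    pos_mask: np.ndarray | None = None,
    neg_mask: np.ndarray | None = None,
) -> tuple[PDStack, PhantomTruth]:
    """Build a phantom stack whose planted regions co-vary with %BP.

    Per-pixel model::

        pd(p, t) = B(p) * (1 + (gain(p) * (hrf (*) bp_norm)(t) + noise(p, t)) / 100)
                   + drift(t)

    where ``bp_norm`` is the %BP series scaled by its maximum absolute
    value, ``B`` is the vessel baseline map, and the noise is white
    Gaussian on the percent scale (multiplicative in pD units, as for
    speckle-dominated power-Doppler).  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    shape = config.shape
    fs = protocol.sampling_rate_hz
    if not np.isclose(bp.sampling_rate_hz, fs):
        raise ValueError("bp must be sampled at the stack frame rate")

    if pos_mask is None or neg_mask is None:
        d_pos, d_neg = default_truth_masks(shape, config.region_fraction)
        pos_mask = d_pos if pos_mask is None else np.asarray(pos_mask, dtype=bool)
        neg_mask = d_neg if neg_mask is None else np.asarray(neg_mask, dtype=bool)
    else:
        pos_mask = np.asarray(pos_mask, dtype=bool)
        neg_mask = np.asarray(neg_mask, dtype=bool)
    if pos_mask.shape != shape or neg_mask.shape != shape:
        raise ValueError("masks must match the grid shape")
    if np.any(pos_mask & neg_mask):
        raise ValueError("pos_mask and neg_mask overlap")

    pct = percent_bp(bp)
    denom = np.abs(pct).max()
    bp_norm = pct / denom if denom > 0 else pct

    if config.identity_kernel:
        kernel = np.array([1.0])
        s = bp_norm
    else:
        kernel = make_hrf_kernel(config.hrf_time_to_peak_s, config.hrf_length_s, fs)
        s = np.convolve(bp_norm, kernel, mode="full")[: bp_norm.size]

    gains = np.zeros(shape)
    gains[pos_mask] = config.gain_pos
    gains[neg_mask] = config.gain_neg

    baseline = _baseline_map(shape, config, rng)

    # percent-scale noise level: explicit, or from the weaker planted signal
    if config.noise_sd is not None:
        noise_sd = config.noise_sd
    elif config.noise_snr is not None:
        s_sd = float(np.std(s))
        weaker_gain = min(abs(config.gain_pos), abs(config.gain_neg))
        noise_sd = weaker_gain * s_sd / config.noise_snr
    else:
        noise_sd = 0.0

    pct_signal = gains[:, :, None] * s[None, None, :]
    if noise_sd > 0:
        pct_signal = pct_signal + rng.normal(0.0, noise_sd, (*shape, s.size))
    data = baseline[:, :, None] * (1.0 + pct_signal / 100.0)

    drift_params = {
        "amplitude": config.drift_amplitude,
        "freqs_hz": list(config.drift_freqs_hz),
    }
    if config.drift_amplitude > 0:
        t = np.arange(data.shape[2]) / fs
        drift = np.zeros_like(t)
        phases = rng.uniform(0, 2 * np.pi, len(config.drift_freqs_hz))
        for f, ph in zip(config.drift_freqs_hz, phases):
            drift += np.sin(2 * np.pi * f * t + ph)
        drift *= config.drift_amplitude / max(len(config.drift_freqs_hz), 1)
        drift_params["phases"] = phases.tolist()
        data = data + drift[None, None, :]

    stack = PDStack(
        data=data,
        frame_rate_hz=fs,
        baseline_frames=protocol.baseline_frames,
        metadata={"kind": "phantom", "seed": seed},
    )
    truth = PhantomTruth(
        pos_mask=pos_mask,
        neg_mask=neg_mask,
        null_mask=~(pos_mask | neg_mask),
        gains=gains,
        hrf_kernel=kernel,
        noise_sd=noise_sd,
        drift_params=drift_params,
        motion_truth=np.zeros((data.shape[2], 2)),
        seed=seed,
        baseline_map=baseline,
        bp_norm=s,
    )
    return stack, truth


def inject_motion(
    stack: PDStack,
    shifts: np.ndarray,
    truth: PhantomTruth | None = None,
    order: int = 3,
) -> PDStack:
    """Translate each frame by its (row, col) sub-pixel shift.

    Spline interpolation with constant-edge (replicate) padding.  If a
    ``truth`` record is given its ``motion_truth`` is updated in place.
    """
    shifts = np.asarray(shifts, dtype=float)
    if shifts.shape != (stack.n_frames, 2):
        raise ValueError("shifts must have shape (n_frames, 2)")
    if not np.all(np.isfinite(shifts)):
        raise ValueError("shifts must be finite")
    if np.any(np.abs(shifts) >= 10.0):
        raise ValueError("|shift| must be < 10 px")

    out = np.empty_like(stack.data)
    for i in range(stack.n_frames):
        if shifts[i, 0] == 0.0 and shifts[i, 1] == 0.0:
            out[:, :, i] = stack.data[:, :, i]
        else:
            out[:, :, i] = ndimage.shift(
                stack.data[:, :, i], shifts[i], order=order, mode="nearest"
            )
    if truth is not None:
        truth.motion_truth = shifts.copy()
    return stack.copy_with(out)
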