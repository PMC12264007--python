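"""Simulated post-beamforming compound-frame blocks (tissue + blood + noise)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["CompoundBlock", "CompoundConfig", "generate_compound_block", "AliasingError"]


class AliasingError(ValueError):
    """Doppler frequency at or above Nyquist for the block frame rate."""


@dataclass
class CompoundBlock:
    """Complex compound-frame stack: (depth_px, width_px, 200) at 500 Hz."""

    frames: np.ndarray
    frame_rate_hz: float = 500.0
    tissue_rank: int = 5
    vessel_mask: np.ndarray | None = None
    doppler_freqs_hz: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be 3D (depth, width, time)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[2]

    def casorati(self) -> np.ndarray:
        """Space x time matrix (pixels as rows)."""
        d, w, t = self.frames.shape
        return self.frames.reshape(d * w, t)


@dataclass(frozen=True)
class CompoundConfig:
    shape: tuple[int, int] = (32, 32)
    n_frames: int = 200
    frame_rate_hz: float = 500.0
    tissue_rank: int = 5
    tissue_amplitude: float = 50.0
    blood_amplitude: float = 1.0
    doppler_freq_range_hz: tuple[float, float] = (30.0, 200.0)
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.tissue_amplitude < self.blood_amplitude:
            raise ValueError("tissue amplitude must be >= blood amplitude")
        if self.doppler_freq_range_hz[1] >= self.frame_rate_hz / 2.0:
            raise AliasingError(
                f"doppler frequency {self.doppler_freq_range_hz[1]} Hz >= Nyquist "
                f"({self.frame_rate_hz / 2.0} Hz)"
            )
        if self.tissue_rank < 0 or self.tissue_rank >= self.n_frames:
            raise ValueError("tissue_rank out of range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _default_vessel_mask(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """A couple of thin curvilinear vessels."""
    d, w = shape
    mask = np.zeros(shape, dtype=bool)
    cols = np.arange(w)
    for frac in (0.35, 0.65):
        rows = frac * d + 0.1 * d * np.sin(2 * np.pi * cols / w + rng.uniform(0, 2 * np.pi))
        ridx = np.clip(np.round(rows).astype(int), 0, d - 1)
        mask[ridx, cols] = True
    return mask


def generate_compound_block(config: CompoundConfig, seed: int = 0) -> CompoundBlock:
    """Simulate one compound block.

    Tissue: sum of ``tissue_rank`` separable components, each a smooth
    spatial pattern times a near-constant temporal course (numerical rank
    of the tissue-only Casorati matrix is at most ``tissue_rank``).
    Blood: vessel-mask pixels rotate in phase at a per-pixel Doppler
    frequency with constant modulus ``blood_amplitude``.  Complex white
    Gaussian noise with total SD ``noise_sd`` is added.  Deterministic
    per seed.
    """
    rng = np.random.default_rng(seed)
    d, w = config.shape
    t = np.arange(config.n_frames) / config.frame_rate_hz

    frames = np.zeros((d, w, config.n_frames), dtype=complex)
    for k in range(config.tissue_rank):
        spat = rng.standard_normal((d, w)) + 1j * rng.standard_normal((d, w))
        spat = ndimage.gaussian_filter(spat.real, 3.0) + 1j * ndimage.gaussian_filter(spat.imag, 3.0)
        norm = np.abs(spat).max()
        if norm > 0:
            spat = spat / norm
        amp = config.tissue_amplitude * 0.6**k
        # slow, tiny temporal modulation: tissue is temporally near-constant
        temporal = 1.0 + 0.01 * np.sin(2 * np.pi * rng.uniform(0.2, 1.0) * t + rng.uniform(0, 2 * np.pi))
        frames += amp * spat[:, :, None] * temporal[None, None, :]

    vessel_mask = _default_vessel_mask(config.shape, rng)
    freqs = np.zeros(config.shape)
    fvals = rng.uniform(*config.doppler_freq_range_hz, int(vessel_mask.sum()))
    freqs[vessel_mask] = fvals
    phases = rng.uniform(0, 2 * np.pi, int(vessel_mask.sum()))
    rot = np.exp(1j * (2 * np.pi * fvals[:, None] * t[None, :] + phases[:, None]))
    blood = np.zeros((d, w, config.n_frames), dtype=complex)
    blood[vessel_mask] = config.blood_amplitude * rot
    frames += blood

    if config.noise_sd > 0:
        sd = config.noise_sd / np.sqrt(2.0)
        frames += rng.normal(0, sd, frames.shape) + 1j * rng.normal(0, sd, frames.shape)

    return CompoundBlock(
        frames=frames,
        frame_rate_hz=config.frame_rate_hz,
        tissue_rank=config.tissue_rank,
        vessel_mask=vessel_mask,
        doppler_freqs_hz=freqs,
    )
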