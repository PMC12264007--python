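"""Percent-change conversion against the baseline window and noise summary."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ..synthetic_data.phantom import PDStack

__all__ = [
    "PercentChangeStack",
    "percent_change",
    "NoiseReductionReport",
    "noise_reduction_report",
]

logger = logging.getLogger(__name__)


@dataclass
class PercentChangeStack:
    """Per-pixel percent change relative to the baseline-window mean.

    ``data`` is zero (and meaningless) outside ``analysis_mask``; pixels
    with non-positive baseline mean are excluded from the mask.
    """

    data: np.ndarray
    baseline_mean_map: np.ndarray
    analysis_mask: np.ndarray
    frame_rate_hz: float = 1.0
    baseline_frames: int = 300

    @property
    def shape_px(self) -> tuple[int, int]:
        return self.data.shape[0], self.data.shape[1]

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


def percent_change(stack: PDStack) -> PercentChangeStack:
    """``100 * (pd(p, t) - B(p)) / B(p)`` with B the baseline-window mean.

    Pixels whose baseline mean is not strictly positive are flagged and
    removed from the analysis mask.
    """
    if stack.baseline_frames < 2:
        raise ValueError("need at least 2 baseline frames")
    baseline = stack.data[:, :, : stack.baseline_frames].mean(axis=2)
    mask = np.isfinite(baseline) & (baseline > 0)
    n_bad = int((~mask).sum())
    if n_bad:
        logger.warning("excluding %d pixels with non-positive baseline mean", n_bad)
    pct = np.zeros_like(stack.data)
    safe = np.where(mask, baseline, 1.0)
    pct[mask] = 100.0 * (stack.data[mask] - baseline[mask, None]) / safe[mask, None]
    return PercentChangeStack(
        data=pct,
        baseline_mean_map=baseline,
        analysis_mask=mask,
        frame_rate_hz=stack.frame_rate_hz,
        baseline_frames=stack.baseline_frames,
    )


@dataclass(frozen=True)
class NoiseReductionReport:
    """Mean +/- SE over pixels of the per-pixel temporal SD, before/after."""

    raw_mean_sd: float
    raw_se_sd: float
    filtered_mean_sd: float
    filtered_se_sd: float
    n_pixels: int


def _sd_summary(data: np.ndarray) -> tuple[float, float, int]:
    sds = data.std(axis=2, ddof=1).ravel()
    n = sds.size
    return float(sds.mean()), float(sds.std(ddof=1) / np.sqrt(n)), n


def noise_reduction_report(raw: PDStack, filtered: PDStack) -> NoiseReductionReport:
    if raw.data.shape != filtered.data.shape:
        raise ValueError("raw and filtered stacks must have matching shapes")
    if raw.n_frames < 2:
        raise ValueError("need at least 2 frames")
    rm, rs, n = _sd_summary(raw.data)
    fm, fs, _ = _sd_summary(filtered.data)
    return NoiseReductionReport(rm, rs, fm, fs, n)
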