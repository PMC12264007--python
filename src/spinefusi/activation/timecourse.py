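"""Region time-courses, range normalizations and group summaries."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..preprocess.percent import PercentChangeStack
from .stats import ActivationMap

__all__ = [
    "RegionTimecourse",
    "region_timecourse",
    "normalize_range",
    "group_stats",
    "peak_and_group_stats",
    "compare_in_out_mask",
]


@dataclass
class RegionTimecourse:
    """Mean +/- SE (over pixels) percent-change series for one mask."""

    time_s: np.ndarray
    mean_pct: np.ndarray
    se_pct: np.ndarray
    mask_id: str
    n_pixels: int


def region_timecourse(
    pct: PercentChangeStack, mask: np.ndarray, mask_id: str = "region"
) -> RegionTimecourse:
    """Per-frame mean and standard error over the mask pixels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pct.shape_px:
        raise ValueError("mask shape does not match stack grid")
    n_px = int(mask.sum())
    if n_px == 0:
        raise ValueError("empty mask")
    series = pct.data[mask]  # (n_px, t)
    mean = series.mean(axis=0)
    if n_px > 1:
        se = series.std(axis=0, ddof=1) / np.sqrt(n_px)
    else:
        se = np.zeros_like(mean)
    return RegionTimecourse(
        time_s=pct.time_s, mean_pct=mean, se_pct=se, mask_id=mask_id, n_pixels=n_px
    )


def normalize_range(series: np.ndarray, target: tuple[float, float] = (0.0, 1.0)) -> np.ndarray:
    """Affine min-max map of ``series`` onto ``target``; extremes attained."""
    x = np.asarray(series, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise ValueError("cannot normalize a constant series")
    a, b = target
    if b <= a:
        raise ValueError("target range must be increasing")
    return a + (x - lo) * (b - a) / (hi - lo)


def group_stats(values: np.ndarray) -> tuple[float, float]:
    """Mean and standard error (SD / sqrt(n)) across subjects; SE = 0 for n = 1."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    mean = float(v.mean())
    se = 0.0 if v.size == 1 else float(v.std(ddof=1) / np.sqrt(v.size))
    return mean, se


def peak_and_group_stats(per_subject: dict[str, np.ndarray]) -> dict[str, dict]:
    """Across-subject mean +/- SE for each named per-subject statistic.

    Input maps statistic name -> per-subject values; the per-subject
    values are retained in the output for dot plots.
    """
    out: dict[str, dict] = {}
    for name, values in per_subject.items():
        mean, se = group_stats(values)
        out[name] = {"mean": mean, "se": se, "values": np.asarray(values, dtype=float)}
    return out


def compare_in_out_mask(
    pct: PercentChangeStack,
    activation: ActivationMap,
    bounds_mask: np.ndarray,
) -> tuple[RegionTimecourse | None, RegionTimecourse | None]:
    """Time-courses of activated pixels inside vs. outside a bounds mask.

    "Activated" is the union of the positive and negative masks; an
    empty side is omitted (None) with a warning.
    """
    bounds_mask = np.asarray(bounds_mask, dtype=bool)
    if bounds_mask.shape != pct.shape_px:
        raise ValueError("bounds_mask must be on the stack grid")
    if activation.pos_mask is None or activation.neg_mask is None:
        raise ValueError("activation masks not computed; run top_fraction_masks first")
    activated = activation.pos_mask | activation.neg_mask

    inside = activated & bounds_mask
    outside = activated & ~bounds_mask
    tc_in = tc_out = None
    if inside.any():
        tc_in = region_timecourse(pct, inside, mask_id="activated_in_bounds")
    else:
        warnings.warn("no activated pixels inside bounds", stacklevel=2)
    if outside.any():
        tc_out = region_timecourse(pct, outside, mask_id="activated_out_of_bounds")
    else:
        warnings.warn("no activated pixels outside bounds", stacklevel=2)
    return tc_in, tc_out
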