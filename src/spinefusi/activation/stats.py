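"""Per-pixel Pearson correlation with %BP, Fisher z, and BH-FDR control."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from ..preprocess.percent import PercentChangeStack

__all__ = ["ActivationMap", "pearson_map", "bh_fdr"]


@dataclass
class ActivationMap:
    """Per-pixel r / z / p (and, once thresholded, q and masks).

    ``z = atanh(r)`` (sign-preserving); ``p`` is the two-sided p-value of
    the t statistic ``r * sqrt((n - 2) / (1 - r^2))`` on ``n - 2``
    degrees of freedom.  Values are NaN outside ``analysis_mask``.
    """

    r: np.ndarray
    z: np.ndarray
    p: np.ndarray
    analysis_mask: np.ndarray
    n_time: int
    q: np.ndarray | None = None
    pos_mask: np.ndarray | None = None
    neg_mask: np.ndarray | None = None
    r_thresholds: tuple[float, float] | None = None


def pearson_map(
    pct: PercentChangeStack,
    bp: np.ndarray,
    window: slice | None = None,
) -> ActivationMap:
    """Correlate every analyzed pixel's series with %BP over ``window``.

    ``window`` defaults to the post-baseline experiment period.  Pixels
    with zero temporal variance are dropped from the analysis mask.
    """
    if window is None:
        window = slice(pct.baseline_frames, pct.n_frames)
    y = np.asarray(bp, dtype=float)[window]
    n = y.size
    if n < 3:
        raise ValueError("correlation window must contain at least 3 frames")
    if n != pct.data[:, :, window].shape[2]:
        raise ValueError("bp series not aligned to stack frames")

    x = pct.data[:, :, window]
    xm = x - x.mean(axis=2, keepdims=True)
    ym = y - y.mean()
    y_ss = float(ym @ ym)
    if y_ss == 0:
        raise ValueError("bp series has zero variance over the window")
    x_ss = np.einsum("ijk,ijk->ij", xm, xm)
    cov = xm @ ym

    # constant series leave rounding residue ~ (eps * |mean|)^2 in x_ss
    var_floor = n * (1e-12 * (1.0 + np.abs(x.mean(axis=2)))) ** 2
    mask = pct.analysis_mask & (x_ss > var_floor)
    shape = pct.shape_px
    r = np.full(shape, np.nan)
    denom = np.sqrt(x_ss[mask] * y_ss)
    r[mask] = cov[mask] / denom
    r[mask] = np.clip(r[mask], -1.0, 1.0)

    z = np.full(shape, np.nan)
    with np.errstate(divide="ignore"):
        z[mask] = np.arctanh(r[mask])

    p = np.full(shape, np.nan)
    rr = r[mask]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rr * np.sqrt((n - 2) / np.maximum(1.0 - rr**2, 0.0))
    pv = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    pv[np.isinf(t)] = 0.0  # |r| == 1 exactly
    p[mask] = pv

    return ActivationMap(r=r, z=z, p=p, analysis_mask=mask, n_time=n)


def bh_fdr(p: np.ndarray, alpha: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Returns ``(reject, q)`` where ``reject[i]`` marks p-values in the
    step-up rejection set (all sorted p with index <= the largest k such
    that ``p(k) <= k * alpha / m``) and ``q`` are the monotone-adjusted
    values ``min_{j >= rank} p(j) * m / j`` (capped at 1).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    ranks = np.arange(1, m + 1)

    q_sorted = np.minimum.accumulate((ranked * m / ranks)[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)

    passing = np.flatnonzero(ranked <= ranks * alpha / m)
    reject_sorted = np.zeros(m, dtype=bool)
    if passing.size:
        reject_sorted[: passing[-1] + 1] = True

    reject = np.empty(m, dtype=bool)
    q = np.empty(m)
    reject[order] = reject_sorted
    q[order] = q_sorted
    return reject, q
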