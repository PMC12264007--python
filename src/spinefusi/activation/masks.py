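"""Top-fraction activation masks among FDR-significant pixels."""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np

from .stats import ActivationMap, bh_fdr

__all__ = ["top_fraction_masks"]

logger = logging.getLogger(__name__)


def top_fraction_masks(
    amap: ActivationMap,
    fraction: float = 0.05,
    alpha: float = 0.01,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Select the strongest positive/negative correlates.

    Among FDR-significant analyzed pixels, the positive mask holds (up
    to) ``ceil(fraction * M)`` pixels with the largest ``r > 0`` where
    ``M`` is the analyzed-pixel count; the negative mask is the mirror
    image.  Returns ``(pos_mask, neg_mask, (r_thr_pos, r_thr_neg))``
    with the attained (data-dependent) r thresholds, and stores q-values
    and masks on ``amap``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    mask = amap.analysis_mask
    m_analyzed = int(mask.sum())
    flat_idx = np.flatnonzero(mask.ravel())
    reject, q = bh_fdr(amap.p.ravel()[flat_idx], alpha=alpha)

    q_map = np.full(amap.p.shape, np.nan)
    q_map.ravel()[flat_idx] = q
    amap.q = q_map

    r_flat = amap.r.ravel()[flat_idx]
    k = math.ceil(fraction * m_analyzed)

    pos_mask = np.zeros(amap.r.shape, dtype=bool)
    neg_mask = np.zeros(amap.r.shape, dtype=bool)
    r_thr_pos = math.nan
    r_thr_neg = math.nan

    if not reject.any():
        warnings.warn("no FDR-significant pixels; returning empty masks", stacklevel=2)
    else:
        pos_cand = np.flatnonzero(reject & (r_flat > 0))
        if pos_cand.size:
            top = pos_cand[np.argsort(r_flat[pos_cand], kind="stable")[::-1][:k]]
            pos_mask.ravel()[flat_idx[top]] = True
            r_thr_pos = float(r_flat[top].min())
        neg_cand = np.flatnonzero(reject & (r_flat < 0))
        if neg_cand.size:
            top = neg_cand[np.argsort(r_flat[neg_cand], kind="stable")[:k]]
            neg_mask.ravel()[flat_idx[top]] = True
            r_thr_neg = float(r_flat[top].max())

    logger.info(
        "top-fraction masks: %d positive, %d negative of %d analyzed "
        "(r thresholds %+0.3f / %+0.3f)",
        int(pos_mask.sum()), int(neg_mask.sum()), m_analyzed, r_thr_pos, r_thr_neg,
    )
    amap.pos_mask = pos_mask
    amap.neg_mask = neg_mask
    amap.r_thresholds = (r_thr_pos, r_thr_neg)
    return pos_mask, neg_mask, (r_thr_pos, r_thr_neg)
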