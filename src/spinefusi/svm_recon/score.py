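"""Test-set reconstruction scoring and beta-map projection."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .svr import SvmModel, predict

__all__ = ["ReconstructionResult", "reconstruct_and_score", "beta_map", "beta_summary"]


@dataclass
class ReconstructionResult:
    """Predicted vs. actual normalized pressure on the held-out frames."""

    test_times: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    mse: float
    subject_id: str = ""


def reconstruct_and_score(
    model: SvmModel,
    X_test: np.ndarray,
    y_test: np.ndarray,
    test_times: np.ndarray,
    subject_id: str = "",
) -> ReconstructionResult:
    """Predict the held-out frames and compute the MSE.

    Results are ordered by the stored time instants so predicted and
    actual curves can be plotted over time.
    """
    y_test = np.asarray(y_test, dtype=float)
    test_times = np.asarray(test_times)
    if y_test.size == 0:
        raise ValueError("empty test set")
    if not (X_test.shape[0] == y_test.size == test_times.size):
        raise ValueError("X_test, y_test and test_times lengths differ")
    order = np.argsort(test_times, kind="stable")
    y_pred = predict(model, np.asarray(X_test, dtype=float)[order])
    y_true = y_test[order]
    mse = float(np.mean((y_true - y_pred) ** 2))
    return ReconstructionResult(
        test_times=test_times[order],
        y_true=y_true,
        y_pred=y_pred,
        mse=mse,
        subject_id=subject_id,
    )


def beta_map(
    beta: np.ndarray | SvmModel,
    pixel_index_map: np.ndarray,
    shape: tuple[int, int],
) -> np.ndarray:
    """Project the flat beta vector back onto the image grid.

    Masked-out pixels are zero; ``grid.ravel()[pixel_index_map]``
    recovers the flat vector exactly.
    """
    vec = beta.beta if isinstance(beta, SvmModel) else np.asarray(beta, dtype=float)
    pixel_index_map = np.asarray(pixel_index_map)
    if vec.size != pixel_index_map.size:
        raise ValueError("beta length does not match pixel index map")
    if pixel_index_map.size and pixel_index_map.max() >= shape[0] * shape[1]:
        raise ValueError("pixel index map exceeds the grid")
    grid = np.zeros(shape)
    grid.ravel()[pixel_index_map] = vec
    return grid


def beta_summary(
    beta: np.ndarray | SvmModel, fraction: float = 0.05
) -> tuple[float, float, np.ndarray]:
    """Signed sum of all betas, of the top-|beta| fraction, and its mask.

    The top set holds the ``ceil(fraction * M)`` coefficients of largest
    magnitude; the returned boolean mask is over the flat beta vector.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    vec = beta.beta if isinstance(beta, SvmModel) else np.asarray(beta, dtype=float)
    sum_total = float(vec.sum())
    k = math.ceil(fraction * vec.size)
    top_idx = np.argsort(np.abs(vec), kind="stable")[::-1][:k]
    mask = np.zeros(vec.size, dtype=bool)
    mask[top_idx] = True
    sum_top = float(vec[mask].sum())
    return sum_total, sum_top, mask
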