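"""Predictor-matrix construction and the seeded 80/20 frame split."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..preprocess.percent import PercentChangeStack

__all__ = ["SplitIndex", "split_80_20", "vectorize"]


@dataclass(frozen=True)
class SplitIndex:
    """Disjoint sorted train/test frame indices covering the experiment."""

    train_times: np.ndarray
    test_times: np.ndarray
    seed: int
    fraction_test: float = 0.2

    def __post_init__(self) -> None:
        train = np.asarray(self.train_times)
        test = np.asarray(self.test_times)
        if np.intersect1d(train, test).size:
            raise ValueError("train and test indices overlap")

    @property
    def n_frames(self) -> int:
        return self.train_times.size + self.test_times.size


def split_80_20(n_frames: int, seed: int, fraction_test: float = 0.2) -> SplitIndex:
    """Uniform random partition with ``|test| = floor(fraction_test * n)``.

    Deterministic per seed.  With the default experiment period of 1254
    frames this yields the 1004 / 250 train/test counts.
    """
    if n_frames < 5:
        raise ValueError("need at least 5 frames to split")
    if not 0 < fraction_test < 1:
        raise ValueError("fraction_test must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_frames)
    n_test = int(np.floor(fraction_test * n_frames))
    test = np.sort(perm[:n_test])
    train = np.sort(perm[n_test:])
    return SplitIndex(train_times=train, test_times=test, seed=seed, fraction_test=fraction_test)


def vectorize(
    pct: PercentChangeStack, window: slice | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Flatten the stack into a (time x pixels) predictor matrix.

    Columns are the analyzed pixels in row-major flat order; the returned
    ``pixel_index_map`` holds the flat grid index of each column, a
    bijection enabling exact inverse reshaping (see ``beta_map``).
    """
    if window is None:
        window = slice(pct.baseline_frames, pct.n_frames)
    if not pct.analysis_mask.any():
        raise ValueError("analysis mask is empty")
    frames = pct.data[:, :, window]
    if frames.shape[2] == 0:
        raise ValueError("empty frame window")
    pixel_index_map = np.flatnonzero(pct.analysis_mask.ravel())
    d, w, t = frames.shape
    x = frames.reshape(d * w, t)[pixel_index_map].T  # (t, n_pixels)
    return np.ascontiguousarray(x), pixel_index_map
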