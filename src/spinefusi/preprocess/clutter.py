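"""SVD clutter filtering of compound blocks.

Strong, slowly varying tissue echoes dominate the largest singular
components of the space x time (Casorati) matrix; zeroing them leaves the
blood signal, whose per-pixel mean squared magnitude is the power-Doppler
value.
"""

from __future__ import annotations

import numpy as np

from ..synthetic_data.compound import CompoundBlock

__all__ = ["svd_clutter_filter"]


def svd_clutter_filter(block: CompoundBlock, cutoff_rank: int = 20) -> np.ndarray:
    """Power-Doppler image from one compound block.

    Zeroes the ``cutoff_rank`` largest singular components of the Casorati
    matrix and returns the per-pixel temporal mean of ``|residual|**2``.
    ``cutoff_rank = 0`` is the identity filter.
    """
    n_t = block.n_frames
    if not 0 <= cutoff_rank < n_t:
        raise ValueError(f"cutoff_rank must be in [0, {n_t}), got {cutoff_rank}")
    cas = block.casorati()
    if cutoff_rank == 0:
        resid = cas
    else:
        u, s, vh = np.linalg.svd(cas, full_matrices=False)
        clutter = (u[:, :cutoff_rank] * s[:cutoff_rank]) @ vh[:cutoff_rank]
        resid = cas - clutter
    power = np.mean(np.abs(resid) ** 2, axis=1)
    d, w, _ = block.frames.shape
    return power.reshape(d, w)
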