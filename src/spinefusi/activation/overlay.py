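"""Signed color overlays on the grayscale mean vascular map."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless, deterministic
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["render_activation_overlay"]


def render_activation_overlay(
    background: np.ndarray,
    values: np.ndarray,
    pos_mask: np.ndarray | None,
    neg_mask: np.ndarray | None,
    out_path: str | Path,
    log_background: bool = True,
    title: str | None = None,
) -> Path:
    """Render ``values`` (signed, e.g. r or beta) over the mean pD map.

    Only pixels inside the union of the masks are colored (warm for
    positive, cool for negative); empty masks give a pure grayscale
    image.  Output bytes are deterministic for identical inputs.
    """
    background = np.asarray(background, dtype=float)
    values = np.asarray(values, dtype=float)
    if background.shape != values.shape:
        raise ValueError("background and value grids must match")
    shown = np.zeros(background.shape, dtype=bool)
    for m in (pos_mask, neg_mask):
        if m is not None:
            if m.shape != background.shape:
                raise ValueError("mask grid does not match background")
            shown |= m.astype(bool)

    bg = np.log1p(np.maximum(background, 0.0)) if log_background else background

    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.imshow(bg, cmap="gray", interpolation="nearest")
    if shown.any():
        vmax = float(np.abs(values[shown]).max()) or 1.0
        overlay = np.ma.masked_where(~shown, values)
        im = ax.imshow(
            overlay, cmap="coolwarm", vmin=-vmax, vmax=vmax, interpolation="nearest"
        )
        fig.colorbar(im, ax=ax, shrink=0.8)
    if title:
        ax.set_title(title)
    ax.set_axis_off()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=120, metadata={"Software": None})
    plt.close(fig)
    return out_path
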