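"""Overlay rendering of thresholded functional blobs on a background volume."""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["render_overlay"]


def render_overlay(
    background: np.ndarray,
    z_map: np.ndarray,
    z_threshold: float,
    path: str | Path,
    slice_index: int | None = None,
) -> Path:
    """Render one axial slice: background in grayscale, |z| >= threshold in
    a signed red/blue overlay.  Saves a PNG and returns its path."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bg = np.asarray(background, dtype=float)
    z = np.asarray(z_map, dtype=float)
    if bg.shape != z.shape:
        raise ValueError(f"background {bg.shape} and z map {z.shape} differ")
    k = slice_index if slice_index is not None else bg.shape[2] // 2
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(bg[:, :, k].T, cmap="gray", origin="lower")
    masked = np.ma.masked_where(np.abs(z[:, :, k]) < z_threshold, z[:, :, k])
    im = ax.imshow(
        masked.T, cmap="coolwarm", origin="lower", alpha=0.8,
        vmin=-np.max(np.abs(z)) or -1, vmax=np.max(np.abs(z)) or 1,
    )
    fig.colorbar(im, ax=ax, label="z")
    ax.set_axis_off()
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
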