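"""Figures: transform decompositions and attribute sweeps as PNG."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .networks import TransformDecomposition


def plot_decomposition(
    input_image: np.ndarray, dec: TransformDecomposition, path, quiver_stride: int = 4
) -> Path:
    """Input, output, velocity-field quiver and intensity-map heatmap."""
    panels = [("input", input_image), ("output", dec.output_image.data[0, 0])]
    vel = dec.velocity if dec.velocity is not None else dec.displacement
    n_cols = 2 + (vel is not None) + (dec.intensity_delta is not None)
    fig, axes = plt.subplots(1, n_cols, figsize=(3 * n_cols, 3))
    axes = np.atleast_1d(axes)
    k = 0
    for title, img in panels:
        axes[k].imshow(img, cmap="gray", vmin=0, vmax=1)
        axes[k].set_title(title)
        k += 1
    if vel is not None:
        v = vel.data[0]
        h, w = v.shape[1:]
        rr, cc = np.meshgrid(
            np.arange(0, h, quiver_stride), np.arange(0, w, quiver_stride), indexing="ij"
        )
        axes[k].imshow(input_image, cmap="gray", vmin=0, vmax=1)
        axes[k].quiver(
            cc, rr, v[1, ::quiver_stride, ::quiver_stride],
            v[0, ::quiver_stride, ::quiver_stride],
            color="red", angles="xy", scale_units="xy",
        )
        axes[k].set_title("V" if dec.velocity is not None else "F")
        k += 1
    if dec.intensity_delta is not None:
        dx = dec.intensity_delta.data[0, 0]
        lim = max(1e-6, np.abs(dx).max())
        im = axes[k].imshow(dx, cmap="coolwarm", vmin=-lim, vmax=lim)
        axes[k].set_title(r"$\Delta x$")
        fig.colorbar(im, ax=axes[k], fraction=0.046)
    for ax in axes:
        ax.set_xticks([])
        ax.set_yticks([])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_attribute_sweep(decs, deltas, path) -> Path:
    """One row of output images across an attribute sweep."""
    fig, axes = plt.subplots(1, len(decs), figsize=(2.2 * len(decs), 2.4))
    for ax, dec, d in zip(np.atleast_1d(axes), decs, deltas):
        ax.imshow(dec.output_image.data[0, 0], cmap="gray", vmin=0, vmax=1)
        ax.set_title(f"{d:+.1f}")
        ax.set_xticks([])
        ax.set_yticks([])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
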