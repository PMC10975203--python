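"""Matplotlib renderings of distance and growth images.

Distance images use a sequential colormap, growth images a diverging one
with a fixed default scale of 0-0.5 m so growth maps of different trees
are directly comparable.  Azimuth runs along x (0-360 deg), elevation
along y (0-90 deg, horizon at the bottom).  Merged images are expanded
back onto the full azimuth axis (each joined element painted across its
member columns) so the panorama geometry is preserved.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .growth import GrowthImage
from .radial import RadialDistanceImage, equal_area_merge_counts

__all__ = [
    "expand_merged",
    "render_distance_image",
    "render_growth_image",
    "render_density",
    "growth_colors",
]


def expand_merged(values, mask, grid, row_lengths):
    """Repaint a merged (ragged) matrix onto the full n_rows x n_cols grid."""
    m = equal_area_merge_counts(grid)
    full_v = np.zeros(grid.shape)
    full_m = np.zeros(grid.shape, dtype=bool)
    for j in range(grid.n_rows):
        g = int(row_lengths[j])
        for i in range(g):
            a = i * int(m[j])
            b = (i + 1) * int(m[j]) if i < g - 1 else grid.n_cols
            full_v[j, a:b] = values[j, i]
            full_m[j, a:b] = mask[j, i]
    return full_v, full_m


def _panorama(values, mask, grid, merged, row_lengths):
    if merged:
        values, mask = expand_merged(values, mask, grid, row_lengths)
    data = np.ma.masked_array(values, mask=~mask)
    return data


def render_distance_image(
    image: RadialDistanceImage, path, cmap: str = "YlOrRd", dpi: int = 130
) -> None:
    data = _panorama(
        image.values, image.mask, image.grid, image.merged, image.row_lengths
    )
    fig, ax = plt.subplots(figsize=(9, 3))
    im = ax.imshow(
        data,
        origin="lower",
        extent=(0, 360, 0, 90),
        aspect="auto",
        cmap=cmap,
    )
    fig.colorbar(im, ax=ax, label="radial distance (m)")
    ax.set_xlabel("azimuth θ (°)")
    ax.set_ylabel("elevation φ (°)")
    ax.set_title(f"{image.tree_id} {image.epoch_label}")
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)


def render_growth_image(
    growth: GrowthImage,
    path,
    vmin: float = 0.0,
    vmax: float = 0.5,
    cmap: str = "RdYlBu_r",
    dpi: int = 130,
) -> None:
    data = _panorama(
        growth.diff, growth.valid_mask, growth.grid, growth.merged, growth.row_lengths
    )
    fig, ax = plt.subplots(figsize=(9, 3))
    im = ax.imshow(
        data,
        origin="lower",
        extent=(0, 360, 0, 90),
        aspect="auto",
        cmap=cmap,
        vmin=vmin,
        vmax=vmax,
    )
    fig.colorbar(im, ax=ax, label="growth (m)")
    ax.set_xlabel("azimuth θ (°)")
    ax.set_ylabel("elevation φ (°)")
    ax.set_title(
        f"{growth.tree_id} {growth.epoch_pair[1]} − {growth.epoch_pair[0]}: "
        f"mean {growth.mean_growth:.3f} m"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)


def render_density(curve, path, dpi: int = 130) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    if curve.degenerate:
        ax.axvline(curve.x[0], color="C1")
    else:
        ax.plot(curve.x, curve.density, color="C1")
        ax.fill_between(curve.x, curve.density, alpha=0.3, color="C1")
    ax.set_xlabel("per-tree mean growth (m)")
    ax.set_ylabel("probability density")
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)


def growth_colors(
    values: np.ndarray, vmin: float = 0.0, vmax: float = 0.5, cmap: str = "RdYlBu_r"
) -> np.ndarray:
    """Map growth values (m) to (N, 3) uint8 RGB on a fixed 0-0.5 m ramp."""
    norm = np.clip((np.asarray(values, float) - vmin) / (vmax - vmin), 0, 1)
    rgba = matplotlib.colormaps[cmap](norm)
    return (rgba[:, :3] * 255).astype(np.uint8)
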