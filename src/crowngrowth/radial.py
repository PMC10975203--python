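"""Furthest-point radial distance images and equal-area reshaping.

The upper hemisphere around a tree center is discretized into angular
cells (:class:`~crowngrowth.geometry.AngularGrid`).  Within each cell,
stray long returns are trimmed with a per-cell distance-percentile
filter, and the radial distance to the furthest remaining point is
stored — that point is taken as the branch end visible in that
direction.  Cells that receive no points are masked, never zero-filled:
zero is a legal distance, absence is not.

Cells shrink with elevation (area of a spherical quadrilateral scales
with cos(phi)), so before epochs are compared each row is reshaped by
joining ``m = round(1 / cos(phi_mid))`` azimuthally adjacent cells,
giving every element of the matrix approximately equal spherical
surface area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .geometry import AngularGrid, SphericalPointSet, cell_indices, to_spherical
from .io import PointCloud, TreeCenter

__all__ = [
    "RadialDistanceImage",
    "filter_cell_outliers",
    "build_radial_image",
    "merge_equal_area",
    "image_from_cloud",
    "DEFAULT_PERCENTILE",
]

#: Default per-cell outlier percentile.  Trims isolated SLAM/noise
#: returns beyond the 99th distance percentile of a cell without
#: touching branch tips in normally populated cells.
DEFAULT_PERCENTILE = 99.0


@dataclass
class RadialDistanceImage:
    """Matrix of furthest-point radial distances per angular cell.

    ``values[j, k]`` is the distance (m) for elevation row ``j`` (row 0
    at the horizon) and azimuth column ``k``; ``mask[j, k]`` is True
    where the cell received points.  After :func:`merge_equal_area`,
    ``merged`` is set, ``merge_counts[j]`` records how many original
    cells were joined per element of row ``j`` and ``row_lengths[j]``
    how many elements remain (trailing columns are structural padding,
    always unmasked).
    """

    grid: AngularGrid
    values: np.ndarray
    mask: np.ndarray
    counts: np.ndarray
    outlier_percentile: float
    tree_id: str
    epoch_label: str
    merged: bool = False
    merge_counts: np.ndarray | None = None
    row_lengths: np.ndarray | None = None
    n_points_used: int = 0

    @property
    def n_populated(self) -> int:
        return int(self.mask.sum())

    @property
    def empty_fraction(self) -> float:
        total = (
            self.grid.n_cells
            if not self.merged
            else int(self.row_lengths.sum())
        )
        return 1.0 - self.n_populated / total

    def compatible_with(self, other: "RadialDistanceImage") -> bool:
        return (
            self.grid == other.grid
            and self.merged == other.merged
            and self.values.shape == other.values.shape
        )


def filter_cell_outliers(distances, percentile: float) -> np.ndarray:
    """Keep the distances at or below the given percentile of the cell.

    The percentile (linear interpolation, as in ``numpy.percentile``)
    of a non-empty set is at least its minimum, so the result is never
    empty; a single value always survives, and ``percentile=100`` is a
    no-op.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValidationError("cannot filter an empty cell")
    if not 50.0 < percentile <= 100.0:
        raise ValidationError(
            f"percentile must be in (50, 100], got {percentile}"
        )
    return d[d <= np.percentile(d, percentile)]


def build_radial_image(
    sph: SphericalPointSet,
    grid: AngularGrid,
    percentile: float = DEFAULT_PERCENTILE,
) -> RadialDistanceImage:
    """Bin spherical points into cells and keep each cell's furthest
    inlier distance.

    Equivalent to applying :func:`filter_cell_outliers` followed by
    ``max`` per cell, but vectorized: points are sorted by (cell, r) and
    the retained maximum is read off the sorted distances at the
    percentile rank, which for sorted data is exactly the largest value
    not exceeding the interpolated percentile.
    """
    if not 50.0 < percentile <= 100.0:
        raise ValidationError(
            f"percentile must be in (50, 100], got {percentile}"
        )
    if len(sph) == 0:
        raise ValidationError("empty spherical point set")
    rows, cols = cell_indices(sph.theta, sph.phi, grid)
    flat = rows * grid.n_cols + cols
    order = np.lexsort((sph.r, flat))
    flat_s = flat[order]
    r_s = sph.r[order]

    uniq, start, count = np.unique(flat_s, return_index=True, return_counts=True)
    # rank of the retained maximum after percentile trimming: with
    # h = (p/100)(n-1) the interpolated percentile lies in
    # [v[floor(h)], v[floor(h)+1]), so the largest retained value is
    # v[floor(h)] (ties collapse to the same value).
    h = (percentile / 100.0) * (count - 1)
    pick = start + np.floor(h).astype(np.intp)

    values = np.zeros(grid.shape)
    mask = np.zeros(grid.shape, dtype=bool)
    counts = np.zeros(grid.shape, dtype=np.intp)
    j, k = uniq // grid.n_cols, uniq % grid.n_cols
    values[j, k] = r_s[pick]
    mask[j, k] = True
    counts[j, k] = count
    return RadialDistanceImage(
        grid=grid,
        values=values,
        mask=mask,
        counts=counts,
        outlier_percentile=float(percentile),
        tree_id=sph.tree_id,
        epoch_label=sph.epoch_label,
        n_points_used=len(sph),
    )


def equal_area_merge_counts(grid: AngularGrid) -> np.ndarray:
    """Cells joined per element for every elevation row.

    ``m_j = round(1 / cos(phi_mid_j))`` with ``phi_mid`` the row-center
    elevation, capped at the row length.  Near the horizon cos ~ 1 and
    rows are unchanged; near the zenith whole rows collapse into a few
    elements.
    """
    mids = grid.row_mid_phi
    m = np.floor(1.0 / np.cos(np.radians(mids)) + 0.5).astype(np.intp)
    return np.minimum(np.maximum(m, 1), grid.n_cols)


def merge_equal_area(image: RadialDistanceImage) -> RadialDistanceImage:
    """Join azimuthally adjacent cells so every element covers roughly
    the same spherical area regardless of elevation.

    Within each row, groups of ``m`` consecutive cells are joined (the
    final group absorbs any remainder).  A joined element takes the
    maximum over its populated members and is masked only if all
    members are masked.
    """
    if image.merged:
        raise ValidationError("image is already equal-area merged")
    grid = image.grid
    m_per_row = equal_area_merge_counts(grid)
    n_groups = np.maximum(grid.n_cols // m_per_row, 1)
    width = int(n_groups.max())

    values = np.zeros((grid.n_rows, width))
    mask = np.zeros((grid.n_rows, width), dtype=bool)
    counts = np.zeros((grid.n_rows, width), dtype=np.intp)
    for jrow in range(grid.n_rows):
        m = int(m_per_row[jrow])
        g = int(n_groups[jrow])
        # group g-1 absorbs the remainder columns
        bounds = [(i * m, (i + 1) * m if i < g - 1 else grid.n_cols) for i in range(g)]
        for i, (a, b) in enumerate(bounds):
            sub_mask = image.mask[jrow, a:b]
            if sub_mask.any():
                values[jrow, i] = image.values[jrow, a:b][sub_mask].max()
                mask[jrow, i] = True
            counts[jrow, i] = image.counts[jrow, a:b].sum()
    return RadialDistanceImage(
        grid=grid,
        values=values,
        mask=mask,
        counts=counts,
        outlier_percentile=image.outlier_percentile,
        tree_id=image.tree_id,
        epoch_label=image.epoch_label,
        merged=True,
        merge_counts=m_per_row,
        row_lengths=n_groups.astype(np.intp),
        n_points_used=image.n_points_used,
    )


def image_from_cloud(
    cloud: PointCloud,
    center: TreeCenter,
    grid: AngularGrid,
    percentile: float = DEFAULT_PERCENTILE,
    merge: bool = True,
    below_center: str = "discard",
) -> RadialDistanceImage:
    """Convenience pipeline: transform, bin, and optionally merge."""
    sph = to_spherical(cloud, center, below_center=below_center)
    image = build_radial_image(sph, grid, percentile)
    return merge_equal_area(image) if merge else image
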