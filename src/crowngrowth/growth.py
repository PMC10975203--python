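"""Cross-epoch growth from radial distance images and orchard summaries.

Branch growth is the cell-wise difference (later minus earlier) between
two radial distance images of the same tree, restricted to cells
populated in *both* epochs — differencing against an empty cell is
undefined.  Because elongation is radial and the binning is angular, a
growing branch end stays in its cell while its stored distance
increases, so the mean of the differences estimates the tree's mean
branch-tip elongation.

Orchard-level statistics follow the per-tree-first convention: each
tree is reduced to its mean difference, then

- ``mu`` / ``ME``: mean of the per-tree means (signed bias),
- ``MAE``: mean of their absolute values,
- ``sigma``: standard deviation across trees of the per-tree means
  (sample, n-1, by default).

A pooled per-cell alternative for ME/MAE is available for sensitivity
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .exceptions import ValidationError
from .geometry import AngularGrid, spherical_to_cartesian
from .io import PointCloud, TreeCenter
from .radial import RadialDistanceImage, equal_area_merge_counts

__all__ = [
    "GrowthImage",
    "OrchardSummary",
    "DensityCurve",
    "compute_growth",
    "summarize_orchard",
    "growth_density",
    "branch_end_points",
    "measure_tree_growth",
]


@dataclass
class GrowthImage:
    """Per-cell radial growth of one tree between two epochs (meters)."""

    grid: AngularGrid
    diff: np.ndarray
    valid_mask: np.ndarray
    tree_id: str
    epoch_pair: tuple[str, str]  # (earlier, later)
    merged: bool
    row_lengths: np.ndarray | None
    mean_growth: float
    sd_growth: float
    n_valid_cells: int

    @property
    def valid_diffs(self) -> np.ndarray:
        return self.diff[self.valid_mask]


@dataclass
class OrchardSummary:
    """Orchard-level growth statistics at one grid resolution."""

    per_tree: pd.DataFrame  # tree_id, mean_growth, sd_growth, n_valid_cells
    mu: float
    sigma: float
    me: float
    mae: float
    resolution: float
    sd_mode: str
    n_trees: int


@dataclass
class DensityCurve:
    """Kernel density estimate over per-tree mean growths.

    When all inputs coincide the KDE is undefined; the curve degenerates
    to a unit point mass flagged by ``degenerate`` with ``x`` holding the
    single location.
    """

    x: np.ndarray
    density: np.ndarray
    degenerate: bool = False

    def integral(self) -> float:
        if self.degenerate:
            return 1.0
        return float(np.trapezoid(self.density, self.x))


def compute_growth(
    later: RadialDistanceImage, earlier: RadialDistanceImage, ddof: int = 1
) -> GrowthImage:
    """Difference two epochs of the same tree (later minus earlier;
    positive = growth)."""
    if later.tree_id != earlier.tree_id:
        raise ValidationError(
            f"tree_id mismatch: {later.tree_id!r} vs {earlier.tree_id!r}"
        )
    if not later.compatible_with(earlier):
        raise ValidationError(
            "images differ in grid resolution or merge state; "
            f"({later.grid}, merged={later.merged}) vs "
            f"({earlier.grid}, merged={earlier.merged})"
        )
    valid = later.mask & earlier.mask
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValidationError(
            f"tree {later.tree_id!r}: no cell is populated in both epochs"
        )
    diff = np.zeros_like(later.values)
    diff[valid] = later.values[valid] - earlier.values[valid]
    d = diff[valid]
    sd = float(np.std(d, ddof=ddof)) if n_valid > ddof else 0.0
    return GrowthImage(
        grid=later.grid,
        diff=diff,
        valid_mask=valid,
        tree_id=later.tree_id,
        epoch_pair=(earlier.epoch_label, later.epoch_label),
        merged=later.merged,
        row_lengths=later.row_lengths,
        mean_growth=float(d.mean()),
        sd_growth=sd,
        n_valid_cells=n_valid,
    )


def summarize_orchard(
    growths,
    sd_mode: str = "sample",
    pooled: bool = False,
) -> OrchardSummary:
    """Aggregate per-tree growth images into orchard statistics.

    ``sd_mode`` selects sample (n-1) or population SD across trees; a
    single-tree orchard has sigma 0 under population SD and NaN
    (undefined) under sample SD.  With ``pooled=True``, ME/MAE are
    computed over all valid cells of all trees instead of per-tree
    means.
    """
    growths = list(growths)
    if not growths:
        raise ValidationError("no growth images to summarize")
    if sd_mode not in ("sample", "population"):
        raise ValidationError(f"sd_mode must be sample|population, got {sd_mode!r}")
    g0 = growths[0]
    for g in growths[1:]:
        if g.grid != g0.grid or g.merged != g0.merged:
            raise ValidationError(
                "growth images mix grid resolutions or merge states"
            )
    per_tree = pd.DataFrame(
        {
            "tree_id": [g.tree_id for g in growths],
            "mean_growth": [g.mean_growth for g in growths],
            "sd_growth": [g.sd_growth for g in growths],
            "n_valid_cells": [g.n_valid_cells for g in growths],
        }
    )
    means = per_tree["mean_growth"].to_numpy()
    ddof = 1 if sd_mode == "sample" else 0
    if means.size > ddof:
        sigma = float(np.std(means, ddof=ddof))
    else:
        sigma = float("nan")
    if pooled:
        alldiffs = np.concatenate([g.valid_diffs for g in growths])
        me = float(alldiffs.mean())
        mae = float(np.abs(alldiffs).mean())
    else:
        me = float(means.mean())
        mae = float(np.abs(means).mean())
    return OrchardSummary(
        per_tree=per_tree,
        mu=float(means.mean()),
        sigma=sigma,
        me=me,
        mae=mae,
        resolution=g0.grid.delta_theta,
        sd_mode=sd_mode,
        n_trees=len(growths),
    )


def growth_density(
    growths, bandwidth: float | str | None = None, n_points: int = 512
) -> DensityCurve:
    """Gaussian KDE of per-tree mean growths (the orchard-level view of
    the per-tree growth distributions)."""
    growths = list(growths)
    if len(growths) < 2:
        raise ValidationError("density estimation needs at least 2 trees")
    means = np.array([g.mean_growth for g in growths], dtype=float)
    if np.ptp(means) == 0.0:
        return DensityCurve(
            x=np.array([means[0]]), density=np.array([np.inf]), degenerate=True
        )
    kde = gaussian_kde(means, bw_method=bandwidth)
    pad = 4.0 * means.std(ddof=0) * kde.factor + 1e-6
    x = np.linspace(means.min() - pad, means.max() + pad, n_points)
    return DensityCurve(x=x, density=kde(x))


def _cell_center_angles(
    image: RadialDistanceImage,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(theta, phi, flat-index pairs) of populated cell centers."""
    grid = image.grid
    jj, kk = np.nonzero(image.mask)
    phi = (jj + 0.5) * grid.delta_phi
    if not image.merged:
        theta = (kk + 0.5) * grid.delta_theta
    else:
        m = equal_area_merge_counts(grid)
        n_groups = np.maximum(grid.n_cols // m, 1)
        starts = kk * m[jj]
        ends = np.where(
            kk < n_groups[jj] - 1, (kk + 1) * m[jj], grid.n_cols
        )
        theta = (starts + ends) / 2.0 * grid.delta_theta
    return theta, phi, (jj, kk)


def branch_end_points(
    image: RadialDistanceImage, center: TreeCenter
) -> PointCloud:
    """Reconstruct one Cartesian branch-end point per populated cell
    (cell-center angles at the stored radial distance)."""
    theta, phi, (jj, kk) = _cell_center_angles(image)
    r = image.values[jj, kk]
    xyz = spherical_to_cartesian(r, theta, phi) + np.asarray(center.c, dtype=float)
    return PointCloud(
        xyz, tree_id=image.tree_id, epoch_label=image.epoch_label
    )


def measure_tree_growth(
    earlier_cloud: PointCloud,
    later_cloud: PointCloud,
    center: TreeCenter,
    grid: AngularGrid,
    percentile: float | None = None,
    merge: bool = True,
    below_center: str = "discard",
) -> GrowthImage:
    """End-to-end per-tree growth from two raw clouds."""
    from .radial import DEFAULT_PERCENTILE, image_from_cloud

    pct = DEFAULT_PERCENTILE if percentile is None else percentile
    earlier = image_from_cloud(
        earlier_cloud, center, grid, pct, merge=merge, below_center=below_center
    )
    later = image_from_cloud(
        later_cloud, center, grid, pct, merge=merge, below_center=below_center
    )
    return compute_growth(later, earlier)
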