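"""Point-cloud and tabular I/O.

All file-format dialects live here so the math core only ever sees
:class:`PointCloud`, :class:`TreeCenter` and plain numpy arrays.

Supported point-cloud formats
-----------------------------
``xyz``
    Plain text, whitespace- or comma-delimited; the first three numeric
    columns are x, y, z in meters, extra columns are ignored (tolerant
    of CloudCompare exports).  Colors are not representable.
``ply``
    ASCII or binary PLY, read/written through :mod:`trimesh`; per-point
    RGB colors are preserved.
``las``
    Uncompressed LAS 1.2, 1 mm coordinate scale on write (below scanner
    accuracy); RGB persisted via point format 2.  LAZ is not supported.

For batch processing, cloud filenames follow ``<tree_id>_<epoch>.<ext>``
and the centers CSV (columns ``tree_id,x,y,z``) is the single source of
tree identity.  Centers must be expressed in the same Cartesian frame as
the clouds.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import _las
from .exceptions import EmptyCloudError, FormatError, ValidationError

__all__ = [
    "PointCloud",
    "TreeCenter",
    "read_point_cloud",
    "write_point_cloud",
    "read_tree_centers",
    "write_tree_centers",
    "write_matrix_csv",
    "read_matrix_csv",
    "parse_cloud_filename",
    "SUPPORTED_FORMATS",
]

SUPPORTED_FORMATS = ("xyz", "ply", "las")

_NA = "NA"


@dataclass
class PointCloud:
    """A single-epoch per-tree point cloud, coordinates in meters."""

    points: np.ndarray  # (N, 3) float64
    tree_id: str = "tree"
    epoch_label: str = "scan1"
    colors: np.ndarray | None = None  # optional (N, 3) uint8

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValidationError(
                f"points must be (N, 3), got shape {self.points.shape}"
            )
        if self.points.shape[0] < 1:
            raise EmptyCloudError(f"tree {self.tree_id!r}: empty point cloud")
        bad = ~np.isfinite(self.points).all(axis=1)
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"tree {self.tree_id!r}: non-finite coordinates at record {idx}"
            )

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class TreeCenter:
    """The trunk-fork point a tree's radial distances are measured from."""

    tree_id: str
    c: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.c) != 3 or not np.isfinite(self.c).all():
            raise ValidationError(
                f"tree {self.tree_id!r}: center coordinates must be 3 finite numbers"
            )


def _infer_format(path: Path, format_hint: str | None) -> str:
    fmt = (format_hint or path.suffix.lstrip(".")).lower()
    if fmt == "laz":
        raise FormatError(
            f"{path}: LAZ-compressed clouds are not supported; "
            "decompress to LAS first"
        )
    if fmt == "txt":
        fmt = "xyz"
    if fmt not in SUPPORTED_FORMATS:
        raise FormatError(
            f"{path}: cannot infer format (supported: {', '.join(SUPPORTED_FORMATS)})"
        )
    return fmt


def _read_xyz(path: Path) -> np.ndarray:
    rows: list[tuple[float, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "//")):
                continue
            parts = line.replace(",", " ").replace(";", " ").split()
            vals: list[float] = []
            for tok in parts:
                try:
                    vals.append(float(tok))
                except ValueError:
                    break  # trailing non-numeric columns are ignored
                if len(vals) == 3:
                    break
            if len(vals) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected at least 3 numeric columns"
                )
            if not all(np.isfinite(vals)):
                raise ValidationError(
                    f"{path}:{lineno}: non-finite coordinate"
                )
            rows.append((vals[0], vals[1], vals[2]))
    if not rows:
        raise EmptyCloudError(f"{path}: no points found")
    return np.asarray(rows, dtype=np.float64)


def _read_ply(path: Path) -> tuple[np.ndarray, np.ndarray | None]:
    import trimesh

    try:
        obj = trimesh.load(str(path), file_type="ply", process=False)
    except Exception as exc:  # trimesh raises assorted types on bad input
        raise FormatError(f"{path}: unreadable PLY ({exc})") from exc
    verts = np.asarray(obj.vertices, dtype=np.float64)
    colors = None
    try:
        if obj.colors is not None and len(obj.colors) == len(verts):
            colors = np.asarray(obj.colors)[:, :3].astype(np.uint8)
    except (AttributeError, ValueError, IndexError):
        colors = None
    return verts, colors


def read_point_cloud(
    path: str | Path,
    format_hint: str | None = None,
    tree_id: str | None = None,
    epoch_label: str | None = None,
) -> PointCloud:
    """Read a per-tree point cloud; format inferred from extension.

    ``tree_id``/``epoch_label`` default to the ``<tree_id>_<epoch>``
    filename convention when parseable, else to the stem.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file not found")
    fmt = _infer_format(path, format_hint)
    colors = None
    if fmt == "xyz":
        pts = _read_xyz(path)
    elif fmt == "ply":
        pts, colors = _read_ply(path)
    else:
        pts, rgb16 = _las.read_las(path)
        if rgb16 is not None:
            colors = (rgb16 // 257).astype(np.uint8)
    if pts.size == 0:
        raise EmptyCloudError(f"{path}: no points found")
    if tree_id is None or epoch_label is None:
        tid, epoch = parse_cloud_filename(path)
        tree_id = tree_id or tid
        epoch_label = epoch_label or epoch
    return PointCloud(pts, tree_id=tree_id, epoch_label=epoch_label, colors=colors)


def write_point_cloud(
    cloud: PointCloud,
    path: str | Path,
    format: str | None = None,
    colors: np.ndarray | None = None,
) -> None:
    """Write a point cloud; per-point RGB persisted for PLY and LAS."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if colors is None:
        colors = cloud.colors
    if colors is not None:
        colors = np.asarray(colors)
        if colors.shape != (len(cloud), 3):
            raise ValidationError(
                f"colors must be ({len(cloud)}, 3), got {colors.shape}"
            )
    if fmt == "xyz":
        if colors is not None:
            raise ValidationError("plain XYZ cannot store per-point colors")
        np.savetxt(path, cloud.points, fmt="%.6f")
    elif fmt == "ply":
        import trimesh

        pc = trimesh.PointCloud(cloud.points, colors=colors)
        pc.export(str(path))
    else:
        rgb16 = None if colors is None else colors.astype(np.uint16) * 257
        _las.write_las(path, cloud.points, rgb16)


def parse_cloud_filename(path: str | Path) -> tuple[str, str]:
    """Split ``<tree_id>_<epoch>.<ext>`` into (tree_id, epoch_label).

    Falls back to (stem, "scan1") when the stem has no underscore.
    """
    stem = Path(path).stem
    if "_" in stem:
        tree_id, epoch = stem.rsplit("_", 1)
        return tree_id, epoch
    return stem, "scan1"


def read_tree_centers(path: str | Path) -> list[TreeCenter]:
    """Read the centers table (CSV with header ``tree_id,x,y,z``)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: unreadable CSV ({exc})") from exc
    missing = {"tree_id", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ValidationError(
            f"{path}: missing column(s) {sorted(missing)} (expected tree_id,x,y,z)"
        )
    centers: list[TreeCenter] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        tid = str(row["tree_id"])
        if tid in seen:
            raise ValidationError(f"{path}: duplicate tree_id {tid!r} at row {i + 2}")
        seen.add(tid)
        try:
            c = (float(row["x"]), float(row["y"]), float(row["z"]))
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"{path}: non-numeric coordinate at row {i + 2}"
            ) from exc
        if not np.isfinite(c).all():
            raise ValidationError(f"{path}: non-finite coordinate at row {i + 2}")
        centers.append(TreeCenter(tid, c))
    return centers


def write_tree_centers(centers: Iterable[TreeCenter], path: str | Path) -> None:
    rows = [{"tree_id": c.tree_id, "x": c.c[0], "y": c.c[1], "z": c.c[2]} for c in centers]
    pd.DataFrame(rows, columns=["tree_id", "x", "y", "z"]).to_csv(path, index=False)


def _image_rows(image) -> list[list[str]]:
    """Rows of string cells for a radial-distance or growth image."""
    if hasattr(image, "diff"):
        values, mask = image.diff, image.valid_mask
    else:
        values, mask = image.values, image.mask
    row_lengths = getattr(image, "row_lengths", None)
    out: list[list[str]] = []
    for j in range(values.shape[0]):
        n = values.shape[1] if row_lengths is None else int(row_lengths[j])
        out.append(
            [
                format(values[j, k], ".9g") if mask[j, k] else _NA
                for k in range(n)
            ]
        )
    return out


def write_matrix_csv(image, path: str | Path) -> None:
    """Write an image matrix as CSV: rows = elevation bins (row 0 at the
    horizon), columns = azimuth bins; empty cells as ``NA``.  Merged
    images have shorter high-elevation rows."""
    with open(path, "w", newline="") as fh:
        csv.writer(fh).writerows(_image_rows(image))


def read_matrix_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a matrix CSV back into (values, populated-mask) arrays.

    Ragged (merged) rows are right-padded; padding cells are unmasked.
    """
    with open(path, newline="") as fh:
        raw = [row for row in csv.reader(fh) if row]
    if not raw:
        raise FormatError(f"{path}: empty matrix file")
    width = max(len(row) for row in raw)
    values = np.zeros((len(raw), width))
    mask = np.zeros((len(raw), width), dtype=bool)
    for j, row in enumerate(raw):
        for k, tok in enumerate(row):
            tok = tok.strip()
            if tok == _NA or tok == "":
                continue
            values[j, k] = float(tok)
            mask[j, k] = True
    return values, mask


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a batch manifest CSV (columns ``tree_id,epoch_label,path``)."""
    df = pd.read_csv(path)
    missing = {"tree_id", "epoch_label", "path"} - set(df.columns)
    if missing:
        raise ValidationError(
            f"{path}: manifest missing column(s) {sorted(missing)}"
        )
    if len(df) == 0:
        raise ValidationError(f"{path}: empty manifest")
    return df
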