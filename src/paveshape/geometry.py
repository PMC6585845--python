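"""Outline primitives for cell and leaf shapes.

An :class:`Outline` is an ordered, implicitly closed, simple polygon in
micrometres, stored in canonical counter-clockwise orientation. This module
provides ingestion from binary masks (pixel-edge contour tracing) and from
long-format CSV, arc-length resampling, and the geometric kernels (area,
perimeter, convex hull, principal-axis extents) that every shape descriptor
downstream depends on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import MultiPoint, Polygon

logger = logging.getLogger("paveshape")

#: Relative eigenvalue tolerance below which a shape is treated as isotropic.
ISOTROPY_TOL = 1e-9


@dataclass(frozen=True)
class Scale:
    """Physical scale of a raster image, in micrometres per pixel."""

    microns_per_pixel: float = 1.0

    def __post_init__(self) -> None:
        if not self.microns_per_pixel > 0:
            raise ValueError(f"microns_per_pixel must be > 0, got {self.microns_per_pixel}")


@dataclass(frozen=True)
class Outline:
    """Closed simple polygon with vertices in micrometres.

    Vertices are canonicalized on construction: consecutive duplicates (and a
    repeated closing vertex) are dropped, and orientation is corrected to
    counter-clockwise (positive signed area). Self-intersecting input is
    rejected.
    """

    vertices: np.ndarray
    label: str = ""
    border_touching: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError(f"vertices must be an (n, 2) array, got shape {v.shape}")
        v = _drop_duplicate_vertices(v)
        if len(v) < 3:
            raise ValueError("an outline needs at least 3 distinct vertices")
        if _signed_area(v) < 0:
            v = v[::-1]
        if not np.isfinite(v).all():
            raise ValueError("outline vertices must be finite")
        if _signed_area(v) <= 0:
            raise ValueError("outline has zero area (degenerate polygon)")
        if not Polygon(v).is_valid:
            raise ValueError(f"outline {self.label!r} is self-intersecting")
        v.setflags(write=False)
        object.__setattr__(self, "vertices", v)

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def closed_vertices(self) -> np.ndarray:
        """Vertices with the first point appended, for closed-path iteration."""
        return np.vstack([self.vertices, self.vertices[:1]])

    def transformed(self, *, rotate: float = 0.0, translate=(0.0, 0.0), scale: float = 1.0) -> "Outline":
        """Return a rigidly moved / uniformly scaled copy (radians, CCW)."""
        c, s = np.cos(rotate), np.sin(rotate)
        R = np.array([[c, -s], [s, c]])
        v = scale * (self.vertices @ R.T) + np.asarray(translate, dtype=float)
        return replace(self, vertices=v)


def _drop_duplicate_vertices(v: np.ndarray) -> np.ndarray:
    keep = np.any(v != np.roll(v, 1, axis=0), axis=1)
    return v[keep]


def _signed_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


# ---------------------------------------------------------------------------
# Geometric kernels
# ---------------------------------------------------------------------------

def polygon_area(outline: Outline) -> float:
    """Enclosed area (shoelace formula), in squared input units."""
    return _signed_area(outline.vertices)


def perimeter(outline: Outline) -> float:
    """Total boundary length of the closed outline."""
    d = np.diff(outline.closed_vertices, axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def centroid(outline: Outline) -> np.ndarray:
    """Area centroid of the polygon."""
    c = Polygon(outline.vertices).centroid
    return np.array([c.x, c.y])


def convex_hull(outline: Outline) -> Outline:
    """Convex hull as an Outline; hull vertices are a subset of the input."""
    hull = MultiPoint(outline.vertices).convex_hull
    if not isinstance(hull, Polygon):
        raise ValueError("convex hull is degenerate: input vertices are collinear")
    v = np.asarray(hull.exterior.coords)[:-1]
    return Outline(v, label=outline.label, border_touching=outline.border_touching)


def resample(outline: Outline, n_points: int) -> Outline:
    """Resample to ``n_points`` vertices equally spaced in arc length.

    The first output vertex coincides with the first input vertex; all output
    vertices lie exactly on the original boundary.
    """
    if n_points < 8:
        raise ValueError(f"n_points must be >= 8, got {n_points}")
    cv = outline.closed_vertices
    seg = np.hypot(*np.diff(cv, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("cannot resample a zero-perimeter outline")
    t = np.linspace(0.0, total, n_points, endpoint=False)
    x = np.interp(t, s, cv[:, 0])
    y = np.interp(t, s, cv[:, 1])
    return replace(outline, vertices=np.column_stack([x, y]))


@dataclass(frozen=True)
class PrincipalExtents:
    """Extents of an outline along and across its principal axis."""

    length: float
    width: float
    angle: float            # radians, principal axis vs. +x
    isotropic: bool = False  # covariance eigenvalues tied; angle forced to 0


def _area_covariance(v: np.ndarray) -> np.ndarray:
    """Second central moments of the filled polygon (per unit area)."""
    x, y = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cr = x * y1 - x1 * y
    A = cr.sum() / 2.0
    cx = ((x + x1) * cr).sum() / (6.0 * A)
    cy = ((y + y1) * cr).sum() / (6.0 * A)
    Ixx = ((x * x + x * x1 + x1 * x1) * cr).sum() / 12.0
    Iyy = ((y * y + y * y1 + y1 * y1) * cr).sum() / 12.0
    Ixy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cr).sum() / 24.0
    return np.array(
        [[Ixx / A - cx * cx, Ixy / A - cx * cy], [Ixy / A - cx * cy, Iyy / A - cy * cy]]
    )


def principal_extents(outline: Outline, method: str = "covariance") -> PrincipalExtents:
    """Length/width of the outline aligned to its long axis.

    ``method="covariance"`` (default) takes the principal axis of the filled
    polygon's second area moments — robust to vertex-density artefacts such
    as the direction-dependent arc length of pixel-edge contours.
    ``method="feret"`` instead uses the maximum-distance chord between hull
    vertices as the long axis.
    """
    v = outline.vertices
    if method == "feret":
        hv = convex_hull(outline).vertices
        d = np.linalg.norm(hv[:, None, :] - hv[None, :, :], axis=-1)
        i, j = np.unravel_index(np.argmax(d), d.shape)
        dx, dy = hv[j] - hv[i]
        angle = float(np.arctan2(dy, dx))
        isotropic = False
    elif method == "covariance":
        cov = _area_covariance(v)
        evals, evecs = np.linalg.eigh(cov)  # ascending
        if evals[1] <= evals[0] * (1 + ISOTROPY_TOL):
            angle, isotropic = 0.0, True
        else:
            ax = evecs[:, 1]
            angle, isotropic = float(np.arctan2(ax[1], ax[0])), False
    else:
        raise ValueError(f"unknown method {method!r}")

    c, s = np.cos(-angle), np.sin(-angle)
    rot = v @ np.array([[c, -s], [s, c]]).T
    ext = rot.max(axis=0) - rot.min(axis=0)
    length, width = float(max(ext)), float(min(ext))
    return PrincipalExtents(length=length, width=width, angle=angle, isotropic=isotropic)


# ---------------------------------------------------------------------------
# Mask ingestion
# ---------------------------------------------------------------------------

#: Default minimum component area (px^2); suppresses segmentation speckle.
DEFAULT_MIN_AREA_PX = 50.0

# 4-connectivity keeps every component's pixel-edge contour a simple ring.
_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def trace_outlines(
    mask: np.ndarray,
    scale: Scale = Scale(1.0),
    min_area: float = DEFAULT_MIN_AREA_PX,
    invert: bool = False,
    label_prefix: str = "component",
) -> list[Outline]:
    """Extract one Outline per connected foreground component of a binary mask.

    The contour follows pixel *edges* (crack contour), so a k-by-k foreground
    square yields a polygon of area exactly k^2 px^2. Foreground is the greater
    of the two pixel values unless ``invert`` is set. Components smaller than
    ``min_area`` (in px^2) are dropped; components touching the image border
    are kept but flagged. Interior holes are ignored (the exterior ring is
    traced).
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got {mask.ndim}-D")
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    values = np.unique(mask)
    if len(values) > 2:
        raise ValueError(
            f"mask must contain exactly two pixel values; found {len(values)}: {values[:10].tolist()}"
        )
    if len(values) == 1:
        # Uniform image: treat as all-background regardless of the value.
        return []
    fg_value = values[0] if invert else values[1]
    fg = mask == fg_value

    labelled, n_comp = ndimage.label(fg, structure=_STRUCTURE_4)
    outlines: list[Outline] = []
    h, w = mask.shape
    for comp in range(1, n_comp + 1):
        rows, cols = np.nonzero(labelled == comp)
        if len(rows) < min_area:
            continue
        touches = bool(rows.min() == 0 or cols.min() == 0 or rows.max() == h - 1 or cols.max() == w - 1)
        poly = shapely.union_all(shapely.box(cols, rows, cols + 1.0, rows + 1.0))
        if isinstance(poly, shapely.MultiPolygon):  # pragma: no cover - 4-conn never splits
            poly = max(poly.geoms, key=lambda g: g.area)
        v = np.asarray(poly.exterior.coords)[:-1] * scale.microns_per_pixel
        name = f"{label_prefix}_{comp}" + ("|border" if touches else "")
        outlines.append(Outline(v, label=name, border_touching=touches))
    return outlines


# ---------------------------------------------------------------------------
# Outline CSV I/O (long format: one row per vertex)
# ---------------------------------------------------------------------------

OUTLINE_CSV_COLUMNS = ["species", "cell_id", "side", "vertex_index", "x_um", "y_um"]


def outlines_to_frame(outlines, species: str = "", side: str = "") -> pd.DataFrame:
    """Long-format vertex table for a list of outlines."""
    parts = []
    for i, o in enumerate(outlines):
        parts.append(
            pd.DataFrame(
                {
                    "species": species,
                    "cell_id": o.label or f"outline_{i + 1}",
                    "side": side,
                    "vertex_index": np.arange(len(o)),
                    "x_um": o.vertices[:, 0],
                    "y_um": o.vertices[:, 1],
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=OUTLINE_CSV_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def frame_to_outlines(df: pd.DataFrame) -> list[tuple[str, str, str, Outline]]:
    """Inverse of :func:`outlines_to_frame`: (species, cell_id, side, Outline) rows."""
    missing = [c for c in OUTLINE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"outline table is missing columns: {missing}")
    out = []
    for (species, cell_id, side), grp in df.groupby(["species", "cell_id", "side"], sort=False):
        grp = grp.sort_values("vertex_index")
        v = grp[["x_um", "y_um"]].to_numpy(dtype=float)
        out.append((str(species), str(cell_id), str(side), Outline(v, label=str(cell_id))))
    return out
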