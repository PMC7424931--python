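"""Voronoi tessellation of a cone mosaic and bound cone density.

Bound cone density divides the number of cones whose Voronoi cells lie
completely inside the ROI by the summed area of those cells, which removes
the boundary bias of naive count/area density: cones at the image edge have
truncated (or infinite) cells and are excluded rather than clipped.

A cell is "bound" iff it is a closed polygon and every one of its vertices
lies inside or on the ROI rectangle [0, width] × [0, height] (inclusive
boundary, within a small numerical tolerance).  Cells are never clipped;
a partially-outside cell is excluded entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Voronoi

from .io import ConePoints, ROIMeta

__all__ = ["VoronoiResult", "BoundDensity", "voronoi_cells", "bound_density"]

# Tolerance for the inclusive on-boundary test (µm); keeps lattice vertices
# that land exactly on the ROI edge bound despite float rounding.
_EDGE_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Too few points or collinear input: no 2-D tessellation exists."""


class NoBoundCellsError(ValueError):
    """The tessellation has no cell fully inside the ROI."""


@dataclass
class VoronoiResult:
    """Per-point Voronoi cell areas (µm²; NaN for unbounded or
    ROI-crossing cells) and bound flags."""

    cell_areas_um2: np.ndarray
    is_bound: np.ndarray

    @property
    def n_bound(self) -> int:
        return int(self.is_bound.sum())


@dataclass(frozen=True)
class BoundDensity:
    """Bound cone count, summed bound Voronoi area and the derived density
    for one ROI and annotator."""

    n_bound: int
    total_bound_area_um2: float
    density_cones_per_mm2: float


def _polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a convex cell; vertices are angularly sorted about
    their centroid first (scipy does not guarantee ring order)."""
    c = vertices.mean(axis=0)
    order = np.argsort(np.arctan2(vertices[:, 1] - c[1], vertices[:, 0] - c[0]))
    v = vertices[order]
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def voronoi_cells(points: ConePoints, roi: ROIMeta | None = None) -> VoronoiResult:
    """Tessellate a cone set and flag cells completely inside the ROI.

    Parameters
    ----------
    points
        ≥ 4 non-collinear cone coordinates (µm).
    roi
        Bounds for the bound-cell test; defaults to ``points.roi``.

    Raises
    ------
    DegenerateGeometryError
        For < 4 points or (near-)collinear input, where no cell can be
        bound.
    """
    roi = roi if roi is not None else points.roi
    coords = points.coords
    n = len(coords)
    if n < 4:
        raise DegenerateGeometryError(f"need ≥ 4 points, got {n}")
    # Collinearity check via the singular values of the centered cloud.
    sv = np.linalg.svd(coords - coords.mean(axis=0), compute_uv=False)
    if sv[1] <= 1e-12 * max(sv[0], 1.0):
        raise DegenerateGeometryError("points are collinear")

    try:
        vor = Voronoi(coords)
    except Exception as e:  # qhull failures on degenerate input
        raise DegenerateGeometryError(str(e)) from e

    areas = np.full(n, np.nan)
    bound = np.zeros(n, dtype=bool)
    lo = -_EDGE_TOL
    hix = roi.width_um + _EDGE_TOL
    hiy = roi.height_um + _EDGE_TOL
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if not region or -1 in region:
            continue  # open cell: extends to infinity
        verts = vor.vertices[region]
        if (
            verts[:, 0].min() >= lo
            and verts[:, 0].max() <= hix
            and verts[:, 1].min() >= lo
            and verts[:, 1].max() <= hiy
        ):
            bound[i] = True
            areas[i] = _polygon_area(verts)
    return VoronoiResult(cell_areas_um2=areas, is_bound=bound)


def bound_density(points: ConePoints, roi: ROIMeta | None = None) -> BoundDensity:
    """Bound cone density of one annotator's mosaic, in cones/mm².

    density = n_bound / Σ(bound cell areas µm²) × 10⁶.

    Raises
    ------
    NoBoundCellsError
        When the tessellation succeeds but every cell touches or crosses
        the ROI border (distinct from degenerate geometry).
    """
    cells = voronoi_cells(points, roi)
    n_bound = cells.n_bound
    if n_bound == 0:
        raise NoBoundCellsError(
            "no Voronoi cell lies completely inside the ROI"
        )
    total = float(np.nansum(np.where(cells.is_bound, cells.cell_areas_um2, 0.0)))
    return BoundDensity(
        n_bound=n_bound,
        total_bound_area_um2=total,
        density_cones_per_mm2=n_bound / total * 1e6,
    )
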