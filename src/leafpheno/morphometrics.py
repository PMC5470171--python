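"""Pavement-cell shape morphometrics and stomatal index.

Leaf epidermal pavement cells have jigsaw-puzzle outlines.  A standard
scalar descriptor of their lobedness is *convexity* (solidity): the cell
area divided by the area of the cell's convex hull.  Convexity is 1 for
convex cells and decreases as lobes deepen; it is invariant to
translation, rotation and uniform scaling.  The stomatal index is the
percentage of guard cells among all epidermal cells and reflects
meristemoid (stomatal-lineage) division activity.

Coordinates are continuous micrometres; no pixel grid is assumed.
The convex hull is computed with Andrew's monotone-chain algorithm and
areas with the shoelace formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CellPolygon",
    "EpidermisCounts",
    "polygon_area",
    "convex_hull",
    "convexity",
    "convexity_vs_area",
    "stomatal_index",
]


def _shoelace(vertices: np.ndarray) -> float:
    x = vertices[:, 0]
    y = vertices[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _segments_intersect(p1, p2, p3, p4) -> np.ndarray:
    """Vectorized proper-intersection test for segment arrays."""

    def cross(o, a, b):
        return (a[..., 0] - o[..., 0]) * (b[..., 1] - o[..., 1]) - (
            a[..., 1] - o[..., 1]
        ) * (b[..., 0] - o[..., 0])

    d1 = cross(p3, p4, p1)
    d2 = cross(p3, p4, p2)
    d3 = cross(p1, p2, p3)
    d4 = cross(p1, p2, p4)
    return (
        ((d1 > 0) & (d2 < 0) | (d1 < 0) & (d2 > 0))
        & ((d3 > 0) & (d4 < 0) | (d3 < 0) & (d4 > 0))
    )


@dataclass(frozen=True)
class CellPolygon:
    """One epidermal cell outline: ordered (x, y) vertices in micrometres.

    The polygon is implicitly closed (first vertex not repeated).  It must
    be simple (non-self-intersecting), have at least three vertices and
    nonzero area; violations raise ``ValueError`` at construction.
    """

    cell_id: str
    vertices: np.ndarray = field(repr=False)

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if len(v) < 3:
            raise ValueError("a polygon needs at least 3 vertices")
        if not np.all(np.isfinite(v)):
            raise ValueError("vertices must be finite")
        object.__setattr__(self, "vertices", v)
        if self._self_intersects():
            raise ValueError(
                f"polygon {self.cell_id!r} is self-intersecting; "
                "traced outlines are rejected, not repaired"
            )
        if abs(_shoelace(v)) == 0.0:
            raise ValueError(f"polygon {self.cell_id!r} has zero area")

    def _self_intersects(self) -> bool:
        v = self.vertices
        n = len(v)
        a = v
        b = np.roll(v, -1, axis=0)
        i, j = np.triu_indices(n, k=2)
        # skip the wrap-around adjacency (first and last edge share a vertex)
        keep = ~((i == 0) & (j == n - 1))
        i, j = i[keep], j[keep]
        if len(i) == 0:
            return False
        return bool(
            np.any(_segments_intersect(a[i], b[i], a[j], b[j]))
        )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass(frozen=True)
class EpidermisCounts:
    """Guard-cell and total epidermal-cell counts from one field of view."""

    n_guard_cells: int
    n_total_epidermal: int

    def __post_init__(self):
        if self.n_guard_cells < 0:
            raise ValueError("guard cell count must be non-negative")
        if self.n_guard_cells > self.n_total_epidermal:
            raise ValueError("guard cells cannot exceed total epidermal cells")


def polygon_area(p: CellPolygon) -> float:
    """Absolute shoelace area in square micrometres (orientation-free)."""
    return abs(_shoelace(p.vertices))


def _monotone_chain(points: np.ndarray) -> np.ndarray:
    """Andrew's monotone-chain convex hull; returns CCW hull vertices.

    Collinear boundary points are dropped.  Raises on degenerate
    (collinear) input.
    """
    pts = np.unique(points, axis=0)
    if len(pts) < 3:
        raise ValueError("degenerate hull: fewer than 3 distinct points")
    # lexicographic sort by (x, y)
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower: list[np.ndarray] = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list[np.ndarray] = []
    for p in pts[::-1]:
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = np.array(lower[:-1] + upper[:-1])
    if len(hull) < 3:
        raise ValueError("degenerate hull: all points collinear")
    return hull


def convex_hull(p: CellPolygon) -> CellPolygon:
    """Convex hull of the vertex set as a new polygon (CCW, collinear
    boundary points dropped)."""
    hull = _monotone_chain(p.vertices)
    return CellPolygon(cell_id=f"{p.cell_id}/hull", vertices=hull)


def convexity(p: CellPolygon) -> float:
    """Cell area divided by convex-hull area; in (0, 1], 1 iff convex."""
    a = polygon_area(p)
    h = polygon_area(convex_hull(p))
    # hull area can only exceed or equal the polygon area
    return min(a / h, 1.0)


def convexity_vs_area(
    cells: list[tuple[CellPolygon, str]],
    n_bins: int = 8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell (area, convexity) pairs and a binned area-convexity curve.

    Areas are binned on a log scale (lobedness scales with cell size, so
    log-spaced bins give comparable occupancy); the curve reports the mean
    convexity per genotype per bin, which lets one ask whether the
    area-convexity relationship differs between genotypes beyond a size
    shift.

    Returns
    -------
    per_cell : DataFrame with columns cell_id, genotype, area_um2, convexity
    curve : DataFrame with columns genotype, bin_center_um2, mean_convexity,
        n_cells
    """
    if not cells:
        raise ValueError("no cells supplied")
    rows = [
        {
            "cell_id": poly.cell_id,
            "genotype": genotype,
            "area_um2": polygon_area(poly),
            "convexity": convexity(poly),
        }
        for poly, genotype in cells
    ]
    per_cell = pd.DataFrame(rows)
    lo = per_cell["area_um2"].min()
    hi = per_cell["area_um2"].max()
    if lo == hi:
        edges = np.array([lo * 0.999, hi * 1.001])
    else:
        edges = np.geomspace(lo, hi * (1 + 1e-12), n_bins + 1)
    idx = np.clip(np.digitize(per_cell["area_um2"], edges) - 1, 0, len(edges) - 2)
    per_cell = per_cell.assign(_bin=idx)
    centers = np.sqrt(edges[:-1] * edges[1:])
    curve = (
        per_cell.groupby(["genotype", "_bin"], sort=True)
        .agg(mean_convexity=("convexity", "mean"), n_cells=("convexity", "size"))
        .reset_index()
    )
    curve["bin_center_um2"] = centers[curve["_bin"]]
    curve = curve[["genotype", "bin_center_um2", "mean_convexity", "n_cells"]]
    return per_cell.drop(columns="_bin"), curve


def stomatal_index(c: EpidermisCounts) -> float:
    """Guard cells as a percentage of all epidermal cells."""
    if c.n_total_epidermal == 0:
        raise ValueError("total epidermal cell count is zero")
    return 100.0 * c.n_guard_cells / c.n_total_epidermal
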