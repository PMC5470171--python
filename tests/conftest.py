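import numpy as np
import pytest
from hypothesis import settings

from leafpheno.morphometrics import CellPolygon

# reproducible property tests: same examples every run
settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


def random_simple_polygon(rng: np.random.Generator, n_min=4, n_max=12) -> CellPolygon:
    """Random star-shaped (hence simple) polygon: random radii at sorted
    random angles around the origin."""
    n = int(rng.integers(n_min, n_max + 1))
    # jittered evenly spaced angles keep every angular gap below pi, so the
    # radial polygon is star-shaped about the origin and therefore simple
    theta = (np.arange(n) + rng.uniform(0.1, 0.9, size=n)) * 2 * np.pi / n
    r = rng.uniform(0.5, 2.0, size=n)
    verts = np.column_stack((r * np.cos(theta), r * np.sin(theta)))
    return CellPolygon(cell_id="rand", vertices=verts)


def brute_force_hull(points: np.ndarray) -> np.ndarray:
    """Independent convex-hull oracle, O(n^3): an ordered pair (i, j) of
    distinct points is a hull edge iff every other point lies on or to
    the left of the directed line i->j; walking the edges yields the hull
    in CCW order.  Returns the canonicalized hull (see
    ``canonical_cycle``)."""
    pts = np.unique(points, axis=0)
    n = len(pts)
    edges = {}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = pts[j] - pts[i]
            cross = d[0] * (pts[:, 1] - pts[i, 1]) - d[1] * (pts[:, 0] - pts[i, 0])
            if np.all(cross >= 0):
                # prefer the farthest collinear endpoint so the walk skips
                # interior collinear points
                if i not in edges or np.linalg.norm(d) > edges[i][1]:
                    edges[i] = (j, float(np.linalg.norm(d)))
    start = min(edges)
    order = [start]
    while True:
        nxt = edges[order[-1]][0]
        if nxt == start:
            break
        order.append(nxt)
    return canonical_cycle(pts[order])


def canonical_cycle(vertices: np.ndarray) -> np.ndarray:
    """Rotate a CCW vertex cycle to start at its lexicographically
    smallest vertex, so two hulls can be compared element-wise."""
    idx = np.lexsort((vertices[:, 1], vertices[:, 0]))[0]
    return np.roll(vertices, -idx, axis=0)


def shoelace_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return abs(0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
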