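"""Voronoi-cell geometry dual to the Delaunay triangulation of cell centers.

The degrees of freedom of the monolayer model are cell *centers* ``r_i``.
Each Voronoi vertex is the circumcenter of a trio of adjacent centers,
written as a barycentric combination ``omega = a r_i + b r_j + c r_k``;
cell polygons are the ordered loops of circumcenters of the Delaunay
triangles incident to a generator, and junctions are the Voronoi edges
shared by two adjacent cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

from .errors import (
    DegenerateGeometryError,
    InvalidConfigurationError,
    InvalidPolygonError,
)

# cell class labels
UNSET = "unset"
INTERIOR = "interior"
BOUNDARY = "boundary"
EXTERIOR = "exterior"

#: default square-domain side (model length units): 25 lattice sites of
#: spacing 450, a calibration at which the stated energy parameters
#: (K = 1, lambda = 15) balance area elasticity against junction tension
DEFAULT_DOMAIN_SIDE = 11250.0
#: default number of lattice points per side (625 cells total)
DEFAULT_N_PER_SIDE = 25
#: default lattice jitter, as a fraction of the lattice spacing
DEFAULT_JITTER = 0.1


@dataclass
class CellCenters:
    """Identified 2D generator points with mobility flags and class labels."""

    ids: np.ndarray
    positions: np.ndarray
    mobile: np.ndarray
    cell_class: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        self.mobile = np.asarray(self.mobile, dtype=bool)
        self.cell_class = np.asarray(self.cell_class, dtype=object)
        n = len(self.ids)
        if len(np.unique(self.ids)) != n:
            raise InvalidConfigurationError("cell ids must be unique")
        if self.positions.shape != (n, 2) or not np.all(np.isfinite(self.positions)):
            raise InvalidConfigurationError("positions must be finite (n, 2)")
        if self.mobile.shape != (n,) or self.cell_class.shape != (n,):
            raise InvalidConfigurationError("flag arrays must have length n")

    def __len__(self) -> int:
        return len(self.ids)

    def check_min_separation(self, min_sep: float) -> None:
        """Raise if any two centers are closer than ``min_sep``."""
        from scipy.spatial import cKDTree

        d, _ = cKDTree(self.positions).query(self.positions, k=2)
        if np.min(d[:, 1]) < min_sep:
            raise InvalidConfigurationError(
                f"minimum center separation {np.min(d[:, 1]):.3g} < {min_sep:.3g}"
            )

    def copy(self) -> "CellCenters":
        return CellCenters(
            self.ids.copy(),
            self.positions.copy(),
            self.mobile.copy(),
            self.cell_class.copy(),
        )


def generate_seed_points(
    n_per_side: int = DEFAULT_N_PER_SIDE,
    domain_side: float = DEFAULT_DOMAIN_SIDE,
    jitter: float = DEFAULT_JITTER,
    seed: int = 0,
) -> CellCenters:
    """Seed ``n_per_side**2`` cell centers on a jittered square lattice.

    Lattice sites sit at cell midpoints ``(i + 1/2) * spacing`` inside
    ``[0, domain_side]^2``; each coordinate is perturbed by a uniform jitter
    of at most ``jitter`` lattice spacings.  Deterministic for a fixed seed.
    All points are returned mobile with class unset.
    """
    if n_per_side < 3:
        raise InvalidConfigurationError("n_per_side must be >= 3")
    if domain_side <= 0:
        raise InvalidConfigurationError("domain_side must be positive")
    if not 0 <= jitter < 0.5:
        raise InvalidConfigurationError("jitter must lie in [0, 0.5)")
    spacing = domain_side / n_per_side
    axis = (np.arange(n_per_side) + 0.5) * spacing
    xx, yy = np.meshgrid(axis, axis, indexing="xy")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    rng = np.random.default_rng(seed)
    pts = pts + rng.uniform(-jitter * spacing, jitter * spacing, pts.shape)
    n = n_per_side * n_per_side
    centers = CellCenters(
        ids=np.arange(n),
        positions=pts,
        mobile=np.ones(n, dtype=bool),
        cell_class=np.full(n, UNSET, dtype=object),
    )
    centers.check_min_separation(1e-6 * domain_side)
    return centers


def compute_vertex(
    r_i: Iterable[float], r_j: Iterable[float], r_k: Iterable[float]
) -> tuple[np.ndarray, float, float, float]:
    """Voronoi vertex (circumcenter) of a trio of adjacent cell centers.

    Returns ``(omega, a, b, c)`` where ``omega = a r_i + b r_j + c r_k``,
    with barycentric weights

    ``a = |r_j - r_k|^2 (r_i - r_j).(r_i - r_k) / D`` (and cyclic),
    ``D = 2 |(r_i - r_j) x (r_j - r_k)|^2``.

    The weights sum to one and ``omega`` is equidistant from the trio.
    """
    ri, rj, rk = (np.asarray(p, dtype=float) for p in (r_i, r_j, r_k))
    dij, dik, djk = ri - rj, ri - rk, rj - rk
    cross = dij[0] * djk[1] - dij[1] * djk[0]  # (ri - rj) x (rj - rk)
    scale2 = max(dij @ dij, dik @ dik, djk @ djk)
    if abs(cross) <= 1e-12 * scale2:
        raise DegenerateGeometryError("collinear trio: circumcenter undefined")
    D = 2.0 * cross * cross
    a = (djk @ djk) * (dij @ dik) / D
    b = (dik @ dik) * ((rj - ri) @ (rj - rk)) / D
    c = (dij @ dij) * ((rk - ri) @ (rk - rj)) / D
    omega = a * ri + b * rj + c * rk
    return omega, float(a), float(b), float(c)


def _circumcenters(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Vectorized circumcenters of Delaunay triangles via the 2x2 linear system."""
    p1 = points[simplices[:, 0]]
    p2 = points[simplices[:, 1]]
    p3 = points[simplices[:, 2]]
    e1 = p2 - p1
    e2 = p3 - p1
    cr = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    scale2 = np.maximum((e1 * e1).sum(1), (e2 * e2).sum(1))
    if np.any(np.abs(cr) <= 1e-12 * scale2):
        bad = np.where(np.abs(cr) <= 1e-12 * scale2)[0]
        raise DegenerateGeometryError(
            f"degenerate (near-collinear) Delaunay triangles: {simplices[bad[:5]].tolist()}"
        )
    # solve 2 (p2-p1).w = |p2|^2-|p1|^2 ; 2 (p3-p1).w = |p3|^2-|p1|^2
    b1 = (p2 * p2).sum(1) - (p1 * p1).sum(1)
    b2 = (p3 * p3).sum(1) - (p1 * p1).sum(1)
    det = 4.0 * cr
    wx = (2.0 * e2[:, 1] * b1 - 2.0 * e1[:, 1] * b2) / det
    wy = (-2.0 * e2[:, 0] * b1 + 2.0 * e1[:, 0] * b2) / det
    return np.column_stack([wx, wy])


def polygon_area(loop: np.ndarray) -> float:
    """Shoelace area of a closed vertex loop; positive for counter-clockwise."""
    loop = np.asarray(loop, dtype=float)
    if loop.ndim != 2 or len(loop) < 3:
        raise InvalidPolygonError("polygon needs at least 3 vertices")
    x, y = loop[:, 0], loop[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_centroid(loop: np.ndarray) -> np.ndarray:
    """Area centroid of a simple polygon (shoelace-weighted)."""
    loop = np.asarray(loop, dtype=float)
    if len(loop) < 3:
        raise InvalidPolygonError("polygon needs at least 3 vertices")
    x, y = loop[:, 0], loop[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    w = x * yn - xn * y
    area = 0.5 * np.sum(w)
    if area == 0:
        raise InvalidPolygonError("zero-area polygon has no centroid")
    cx = np.sum((x + xn) * w) / (6.0 * area)
    cy = np.sum((y + yn) * w) / (6.0 * area)
    return np.array([cx, cy])


@dataclass
class Junction:
    """Voronoi edge shared by two adjacent cells."""

    cell_i: int
    cell_j: int
    v1: int  # triangle (= vertex) index
    v2: int
    length: float


@dataclass
class Tessellation:
    """Voronoi vertices, ordered cell polygons and junctions for a center set.

    ``vertices[t]`` is the circumcenter of Delaunay triangle ``simplices[t]``;
    ``cell_loops[i]`` lists the triangle indices around bounded generator ``i``
    in counter-clockwise order.  Cells whose generators lie on the convex hull
    have unbounded Voronoi regions and carry no loop or area.
    """

    points: np.ndarray
    simplices: np.ndarray
    vertices: np.ndarray
    cell_loops: dict
    junctions: list
    areas: np.ndarray
    bounded: np.ndarray
    _junc_by_cell: dict = field(default_factory=dict, repr=False)

    @property
    def vertex_count(self) -> dict:
        return {i: len(loop) for i, loop in self.cell_loops.items()}

    def cell_polygon(self, i: int) -> np.ndarray:
        """Counter-clockwise vertex coordinates of bounded cell ``i``."""
        return self.vertices[self.cell_loops[i]]

    def cell_junctions(self, i: int) -> list:
        """Junction records involving cell ``i``."""
        return [self.junctions[k] for k in self._junc_by_cell.get(i, [])]

    def neighbors(self, i: int) -> list:
        return [
            j.cell_j if j.cell_i == i else j.cell_i for j in self.cell_junctions(i)
        ]

    def cells_dataframe(self, cell_class: np.ndarray | None = None) -> pd.DataFrame:
        rows = []
        for i, loop in sorted(self.cell_loops.items()):
            rows.append(
                {
                    "cell_id": i,
                    "cell_class": None if cell_class is None else cell_class[i],
                    "area": self.areas[i],
                    "n_vertices": len(loop),
                }
            )
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        payload = {
            "points": self.points.tolist(),
            "vertices": self.vertices.tolist(),
            "cell_loops": {str(i): np.asarray(l).tolist() for i, l in self.cell_loops.items()},
            "junctions": [
                [j.cell_i, j.cell_j, j.v1, j.v2, j.length] for j in self.junctions
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _delaunay_edges(tri: Delaunay) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interior Delaunay edges, each once.

    Returns ``(cells, t1, t2)``: the generator pair across each edge and the
    two incident triangles whose circumcenters bound the dual Voronoi edge.
    """
    T = len(tri.simplices)
    tidx = np.repeat(np.arange(T), 3)
    mloc = np.tile(np.arange(3), T)
    nb = tri.neighbors.ravel()
    keep = nb > tidx  # interior edges, enumerated once; hull edges (nb == -1) drop
    t1 = tidx[keep]
    t2 = nb[keep]
    other = np.array([[1, 2], [2, 0], [0, 1]])
    cells = tri.simplices[t1[:, None], other[mloc[keep]]]
    return cells, t1, t2


def build_tessellation(centers: CellCenters) -> Tessellation:
    """Assemble the Voronoi tessellation dual to the Delaunay triangulation.

    One vertex per Delaunay triangle (its circumcenter), ordered CCW loops for
    every bounded cell, and one junction record per adjacent bounded cell pair.
    """
    pts = centers.positions
    if len(pts) < 4:
        raise InvalidConfigurationError("need at least 4 centers")
    tri = Delaunay(pts)
    verts = _circumcenters(pts, tri.simplices)
    hull = np.zeros(len(pts), dtype=bool)
    hull[np.unique(tri.convex_hull)] = True

    incident: dict[int, list[int]] = {}
    for t, simplex in enumerate(tri.simplices):
        for i in simplex:
            incident.setdefault(int(i), []).append(t)

    cell_loops: dict[int, np.ndarray] = {}
    areas = np.full(len(pts), np.nan)
    for i, ts in incident.items():
        if hull[i]:
            continue
        vv = verts[ts]
        ang = np.arctan2(vv[:, 1] - pts[i, 1], vv[:, 0] - pts[i, 0])
        order = np.argsort(ang)
        loop = np.asarray(ts)[order]
        cell_loops[i] = loop
        areas[i] = polygon_area(verts[loop])

    edge_cells, t1, t2 = _delaunay_edges(tri)
    lengths = np.linalg.norm(verts[t1] - verts[t2], axis=1)
    junctions = []
    junc_by_cell: dict[int, list[int]] = {}
    for k in range(len(t1)):
        ci, cj = int(edge_cells[k, 0]), int(edge_cells[k, 1])
        junctions.append(Junction(ci, cj, int(t1[k]), int(t2[k]), float(lengths[k])))
        junc_by_cell.setdefault(ci, []).append(k)
        junc_by_cell.setdefault(cj, []).append(k)

    return Tessellation(
        points=pts.copy(),
        simplices=tri.simplices.copy(),
        vertices=verts,
        cell_loops=cell_loops,
        junctions=junctions,
        areas=areas,
        bounded=~hull,
        _junc_by_cell=junc_by_cell,
    )
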