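"""Monolayer energy, forces on cell centers, and relaxation to equilibrium.

The model assigns each Voronoi cell an area-elastic energy with a global
prestretch ``g`` (condensation tendency) and per-junction line tensions, and
evolves cell centers down the energy gradient.  Boundary cells (the outermost
demarcated ring) carry a reduced stiffness ``rho * K`` and a reduced
prestretch ``rho_g * g``; their centers are fixed after initialization, but
their polygons keep deforming and so keep exerting forces on interior cells.

Two phases share one engine:

* ``initialization`` — prestretch off (g = 1), an extra rim tension
  ``lambda_out`` on junctions between demarcated and outside cells rounds the
  pattern border, and a soft global area penalty ``k_b`` keeps the demarcated
  area near its seeded value.
* ``main`` — prestretch, stiffness and contractility differentials on;
  junction tension acts on every junction between two non-exterior cells.

Each cell's energy counts its own junctions, so a shared junction contributes
twice its tension-times-length to the total: the default tension is
interpreted on that convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import Delaunay, QhullError

from . import tessellation as tess
from .errors import (
    DegenerateGeometryError,
    InvalidConfigurationError,
    InvalidStateError,
)
from .tessellation import (
    BOUNDARY,
    CellCenters,
    EXTERIOR,
    INTERIOR,
    Tessellation,
    build_tessellation,
    generate_seed_points,
)

PHASE_INIT = "initialization"
PHASE_MAIN = "main"

#: demarcation radius calibrated so the circular pattern captures 120-124
#: of the 625 seeded cells (about 121 on average): 6.23 lattice spacings,
#: the analogue of the 172-um circular micropattern radius
DEFAULT_PATTERN_RADIUS = 2803.5


@dataclass
class MechanicsParams:
    """Mechanical parameters of the monolayer energy.

    ``K_interior`` is the area stiffness of interior cells; boundary cells use
    ``rho * K_interior``.  ``g`` is the prestretch (0 < g <= 1) shrinking the
    intrinsic cell area; boundary cells use ``rho_g * g``.  ``lam`` is the
    junction tension, ``lambda_out`` the extra rim tension used only while
    rounding the border, and ``k_b`` the global area-penalty stiffness of the
    initialization phase.
    """

    K_interior: float = 1.0
    rho: float = 1.0
    g: float = 1.0
    rho_g: float = 1.0
    lam: float = 15.0
    lambda_out: float = 20.0
    k_b: float = 0.1
    tension_eps: float = 4.5
    core_radius: float = 135.0
    core_stiffness: float = 5.0
    A0_per_cell: np.ndarray | None = None
    A0_total: float | None = None

    def __post_init__(self) -> None:
        for name in ("rho", "g", "rho_g"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise InvalidConfigurationError(f"{name} must lie in (0, 1], got {v}")
        for name in (
            "K_interior",
            "lam",
            "lambda_out",
            "k_b",
            "tension_eps",
            "core_radius",
            "core_stiffness",
        ):
            if getattr(self, name) < 0:
                raise InvalidConfigurationError(f"{name} must be >= 0")
        if self.A0_per_cell is not None and np.any(
            np.asarray(self.A0_per_cell)[np.isfinite(self.A0_per_cell)] <= 0
        ):
            raise InvalidConfigurationError("intrinsic areas must be positive")

    def effective(self, cell_class: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell effective stiffness and prestretch for the main phase."""
        K = np.where(cell_class == BOUNDARY, self.rho * self.K_interior, self.K_interior)
        g = np.where(cell_class == BOUNDARY, self.rho_g * self.g, self.g)
        return K.astype(float), g.astype(float)


@dataclass
class ConfinementSpec:
    """Circular or annular micropattern demarcated inside the square domain."""

    shape: str = "circle"
    outer_radius: float = DEFAULT_PATTERN_RADIUS
    inner_radius: float = 0.0
    center: tuple[float, float] = (
        tess.DEFAULT_DOMAIN_SIDE / 2.0,
        tess.DEFAULT_DOMAIN_SIDE / 2.0,
    )

    def __post_init__(self) -> None:
        if self.shape not in ("circle", "annulus"):
            raise InvalidConfigurationError(f"unknown pattern shape {self.shape!r}")
        if self.outer_radius <= 0:
            raise InvalidConfigurationError("outer_radius must be positive")
        if self.shape == "annulus" and not 0 < self.inner_radius < self.outer_radius:
            raise InvalidConfigurationError("annulus needs 0 < inner < outer radius")

    def demarcate(self, positions: np.ndarray) -> np.ndarray:
        """Boolean mask of centers inside the pattern region."""
        r = np.linalg.norm(positions - np.asarray(self.center), axis=1)
        inside = r <= self.outer_radius
        if self.shape == "annulus":
            inside &= r >= self.inner_radius
        return inside


@dataclass
class SimulationState:
    """Cell centers plus parameters, pattern and bookkeeping of one run."""

    centers: CellCenters
    params: MechanicsParams
    pattern: ConfinementSpec
    phase: str = PHASE_MAIN
    step_count: int = 0
    energy: float = np.nan
    energy_trace: list = field(default_factory=list)
    converged: bool = False
    warning: str | None = None
    _tess: Tessellation | None = field(default=None, repr=False)

    @property
    def tessellation(self) -> Tessellation:
        if self._tess is None:
            self._tess = build_tessellation(self.centers)
        return self._tess

    def invalidate(self) -> None:
        self._tess = None

    @property
    def demarcated(self) -> np.ndarray:
        return np.isin(self.centers.cell_class, (INTERIOR, BOUNDARY))


# ---------------------------------------------------------------------------
# per-cell energy (transparent reference form)
# ---------------------------------------------------------------------------


def cell_energy(cell: dict, params: MechanicsParams, phase: str = PHASE_MAIN) -> float:
    """Energy of one cell from its record.

    ``cell`` carries ``area``, ``cell_class``, ``A0``, the lengths of its
    tensioned junctions ``junction_lengths`` and, in the initialization phase,
    its rim-junction lengths ``rim_lengths``.
    """
    A = cell["area"]
    if not A > 0:
        raise InvalidStateError(f"cell {cell.get('id')} has non-positive area {A}")
    A0 = cell["A0"]
    if phase == PHASE_INIT:
        K_eff, g_eff = 1.0, 1.0
    else:
        is_boundary = cell.get("cell_class") == BOUNDARY
        K_eff = params.rho * params.K_interior if is_boundary else params.K_interior
        g_eff = params.rho_g * params.g if is_boundary else params.g
    gA0 = g_eff * A0
    e = 0.5 * K_eff * gA0 * (A / gA0 - 1.0) ** 2
    eps = params.tension_eps

    def _smooth_len(lengths: np.ndarray) -> float:
        # tension length with a small regularization keeping the energy
        # smooth through zero-length junctions (topology flips)
        l = np.asarray(lengths, dtype=float)
        return float(np.sum(np.sqrt(l * l + eps * eps) - eps))

    e += params.lam * _smooth_len(cell.get("junction_lengths", ()))
    if phase == PHASE_INIT:
        e += params.lambda_out * _smooth_len(cell.get("rim_lengths", ()))
    return float(e)


def _cell_records(state: SimulationState, phase: str = PHASE_MAIN) -> list[dict]:
    """Per-cell records for the energy set (the demarcated cells).

    Tension acts on junctions shared with another demarcated cell; during
    initialization each demarcated cell's junctions crossing the pattern
    border additionally carry the rim tension.
    """
    t = state.tessellation
    cls = state.centers.cell_class
    demarc = state.demarcated
    in_energy = demarc
    records = []
    for i in np.where(in_energy)[0]:
        tensioned, rim = [], []
        for j in t.cell_junctions(int(i)):
            other = j.cell_j if j.cell_i == i else j.cell_i
            if demarc[i] and demarc[other]:
                tensioned.append(j.length)
            if phase == PHASE_INIT and demarc[i] and not demarc[other]:
                rim.append(j.length)
        records.append(
            {
                "id": int(i),
                "cell_class": cls[i],
                "area": float(t.areas[i]),
                "A0": float(state.params.A0_per_cell[i]),
                "junction_lengths": tensioned,
                "rim_lengths": rim,
            }
        )
    return records


def total_energy(state: SimulationState, phase: str | None = None) -> float:
    """Total monolayer energy: sum of per-cell energies (plus, during
    initialization, the global area penalty on the demarcated region)."""
    phase = phase or state.phase
    records = _cell_records(state, phase)
    e = sum(cell_energy(r, state.params, phase) for r in records)
    if phase == PHASE_INIT:
        demarc = state.demarcated
        A = sum(r["area"] for r in records if demarc[r["id"]])
        A0 = state.params.A0_total
        e += 0.5 * state.params.k_b * A0 * (A / A0 - 1.0) ** 2
    p = state.params
    if p.core_stiffness > 0:
        t = state.tessellation
        pos = state.centers.positions
        for j in t.junctions:
            d = float(np.linalg.norm(pos[j.cell_i] - pos[j.cell_j]))
            if d < p.core_radius:
                e += 0.5 * p.core_stiffness * (p.core_radius - d) ** 2
    return float(e)


# ---------------------------------------------------------------------------
# vectorized energy + gradient engine
# ---------------------------------------------------------------------------


class _Engine:
    """Vectorized energy/force evaluation for a fixed cell classification.

    Rebuilds the Delaunay structure from scratch for every candidate point
    set, so neighbor exchanges are handled implicitly.
    """

    def __init__(self, state: SimulationState, phase: str):
        self.phase = phase
        self.params = state.params
        cls = state.centers.cell_class
        self.demarc = np.isin(cls, (INTERIOR, BOUNDARY))
        self.movable = state.centers.mobile.copy()
        n = len(cls)
        self.energy_mask = self.demarc
        if phase == PHASE_INIT:
            # uniform stiffness, no prestretch while rounding the border
            self.K_eff = np.ones(n)
            self.g_eff = np.ones(n)
        else:
            self.K_eff, self.g_eff = self.params.effective(cls)
        self.A0 = np.asarray(self.params.A0_per_cell, dtype=float)

    def __call__(self, points: np.ndarray) -> tuple[float, np.ndarray]:
        """Return (total energy, forces).  Raises QhullError/LinAlgError on
        degenerate geometry; the relaxation loop treats that as a rejected
        step."""
        p = self.params
        tri = Delaunay(points)
        S = tri.simplices
        C = tess._circumcenters(points, S)
        edge_cells, t1, t2 = tess._delaunay_edges(tri)

        c1 = C[t1]
        c2 = C[t2]
        # --- areas: fan decomposition of each Voronoi cell around its generator
        r0 = points[edge_cells[:, 0]]
        r1 = points[edge_cells[:, 1]]
        u0, v0 = c1 - r0, c2 - r0
        u1, v1 = c1 - r1, c2 - r1
        cr0 = u0[:, 0] * v0[:, 1] - u0[:, 1] * v0[:, 0]
        cr1 = u1[:, 0] * v1[:, 1] - u1[:, 1] * v1[:, 0]
        s0 = np.sign(cr0)
        s1 = np.sign(cr1)
        n = len(points)
        areas = np.bincount(
            edge_cells[:, 0], weights=0.5 * s0 * cr0, minlength=n
        ) + np.bincount(edge_cells[:, 1], weights=0.5 * s1 * cr1, minlength=n)

        emask = self.energy_mask
        A = areas[emask]
        if np.any(A <= 0):
            raise InvalidStateError("non-positive cell area in energy set")
        gA0 = self.g_eff[emask] * self.A0[emask]
        E = float(np.sum(0.5 * self.K_eff[emask] * gA0 * (A / gA0 - 1.0) ** 2))

        # --- tension coefficients per Voronoi edge.  Tension acts on the
        # microtissue's intercellular junctions: each demarcated cell counts
        # each of its tensioned junctions once, so junctions shared by two
        # demarcated cells count twice.  During initialization the rim
        # junctions (pattern border) additionally carry lambda_out.
        d0 = self.demarc[edge_cells[:, 0]]
        d1 = self.demarc[edge_cells[:, 1]]
        tau = np.zeros(len(t1))
        tau[d0 & d1] = 2.0 * p.lam
        if self.phase == PHASE_INIT:
            tau[d0 ^ d1] += p.lambda_out
        ell = np.linalg.norm(c1 - c2, axis=1)
        eps = p.tension_eps
        ell_s = np.sqrt(ell * ell + eps * eps)
        E += float(np.sum(tau * (ell_s - eps)))

        # --- pressure-like dE/dA per cell
        dEdA = np.zeros(n)
        dEdA[emask] = self.K_eff[emask] * (A / gA0 - 1.0)
        if self.phase == PHASE_INIT:
            # global area penalty acts on the demarcated (pattern) area only
            At = float(np.sum(areas[self.demarc]))
            A0t = p.A0_total
            E += 0.5 * p.k_b * A0t * (At / A0t - 1.0) ** 2
            dEdA[self.demarc] += p.k_b * (At / A0t - 1.0)

        # --- soft-core repulsion between adjacent generator pairs keeps the
        # centers -> tessellation map well conditioned (sliver triangles)
        d_vec = points[edge_cells[:, 0]] - points[edge_cells[:, 1]]
        d_gen = np.linalg.norm(d_vec, axis=1)
        pen = np.maximum(p.core_radius - d_gen, 0.0)
        E += 0.5 * p.core_stiffness * float(np.sum(pen * pen))

        # --- gradient wrt circumcenters and (directly) generators
        T = len(S)
        tl = tau / ell_s
        glx = (c1[:, 0] - c2[:, 0]) * tl
        gly = (c1[:, 1] - c2[:, 1]) * tl

        q0 = 0.5 * s0 * dEdA[edge_cells[:, 0]]
        q1 = 0.5 * s1 * dEdA[edge_cells[:, 1]]
        # d cross(u, v)/dc1 = (v_y, -v_x); /dc2 = (-u_y, u_x); /dr = (u_y - v_y, v_x - u_x)
        gc1x = q0 * v0[:, 1] + q1 * v1[:, 1] + glx
        gc1y = -q0 * v0[:, 0] - q1 * v1[:, 0] + gly
        gc2x = -q0 * u0[:, 1] - q1 * u1[:, 1] - glx
        gc2y = q0 * u0[:, 0] + q1 * u1[:, 0] - gly
        Gcx = np.bincount(t1, weights=gc1x, minlength=T) + np.bincount(
            t2, weights=gc2x, minlength=T
        )
        Gcy = np.bincount(t1, weights=gc1y, minlength=T) + np.bincount(
            t2, weights=gc2y, minlength=T
        )
        Grx = np.bincount(
            edge_cells[:, 0], weights=q0 * (u0[:, 1] - v0[:, 1]), minlength=n
        ) + np.bincount(
            edge_cells[:, 1], weights=q1 * (u1[:, 1] - v1[:, 1]), minlength=n
        )
        Gry = np.bincount(
            edge_cells[:, 0], weights=q0 * (v0[:, 0] - u0[:, 0]), minlength=n
        ) + np.bincount(
            edge_cells[:, 1], weights=q1 * (v1[:, 0] - u1[:, 0]), minlength=n
        )
        act = pen > 0
        if np.any(act):
            coef = -p.core_stiffness * pen[act] / np.maximum(d_gen[act], 1e-12)
            gx = coef * d_vec[act, 0]
            gy = coef * d_vec[act, 1]
            i0, i1 = edge_cells[act, 0], edge_cells[act, 1]
            Grx += np.bincount(i0, weights=gx, minlength=n) - np.bincount(
                i1, weights=gx, minlength=n
            )
            Gry += np.bincount(i0, weights=gy, minlength=n) - np.bincount(
                i1, weights=gy, minlength=n
            )

        # --- chain rule through the circumcenter of each triangle
        p1 = points[S[:, 0]]
        p2 = points[S[:, 1]]
        p3 = points[S[:, 2]]
        e1 = p2 - p1
        e2 = p3 - p1
        det = 4.0 * (e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
        # solve M^T y = Gc with M = 2 [e1; e2]
        y1 = (2.0 * e2[:, 1] * Gcx - 2.0 * e2[:, 0] * Gcy) / det
        y2 = (-2.0 * e1[:, 1] * Gcx + 2.0 * e1[:, 0] * Gcy) / det
        w1 = -2.0 * (y1 + y2)
        Grx += (
            np.bincount(S[:, 0], weights=w1 * (p1[:, 0] - C[:, 0]), minlength=n)
            + np.bincount(S[:, 1], weights=2.0 * y1 * (p2[:, 0] - C[:, 0]), minlength=n)
            + np.bincount(S[:, 2], weights=2.0 * y2 * (p3[:, 0] - C[:, 0]), minlength=n)
        )
        Gry += (
            np.bincount(S[:, 0], weights=w1 * (p1[:, 1] - C[:, 1]), minlength=n)
            + np.bincount(S[:, 1], weights=2.0 * y1 * (p2[:, 1] - C[:, 1]), minlength=n)
            + np.bincount(S[:, 2], weights=2.0 * y2 * (p3[:, 1] - C[:, 1]), minlength=n)
        )

        F = -np.column_stack([Grx, Gry])
        F[~self.movable] = 0.0
        return E, F


def forces(state: SimulationState, phase: str | None = None) -> np.ndarray:
    """Force ``-dE/dr`` on every movable center (zero on fixed centers)."""
    engine = _Engine(state, phase or state.phase)
    _, F = engine(state.centers.positions)
    return F


def relax(
    state: SimulationState,
    phase: str | None = None,
    dt: float = 0.01,
    tol: float = 1e-6,
    max_steps: int = 200_000,
    dt_max: float | None = None,
    stall_window: int = 200,
    stall_rtol: float = 1e-9,
) -> SimulationState:
    """Explicit-Euler gradient descent on cell centers, in place.

    A step is accepted only if the tessellation stays valid and the energy
    does not increase; otherwise the step size is halved and the step
    retried.  Accepted steps gently re-grow the step size.

    Terminates when the largest force on a movable center drops below
    ``tol`` (smooth minimum), or when the energy decrease over the last
    ``stall_window`` accepted steps falls below ``stall_rtol * (1 + |E|)``.
    The second rule matters in tension-dominated states, whose minima can
    sit at topology-change kinks where the force never vanishes; the
    configuration is equilibrated there even though the force criterion is
    unattainable.  Hitting ``max_steps`` sets ``state.warning`` instead of
    raising.
    """
    if dt <= 0:
        raise InvalidConfigurationError("dt must be positive")
    phase = phase or state.phase
    engine = _Engine(state, phase)
    pts = state.centers.positions.copy()
    dt_max = dt_max if dt_max is not None else 10.0 * dt
    E, F = engine(pts)
    trace = [E]
    fixed = ~engine.movable
    fixed_pts = pts[fixed].copy()
    steps = 0
    state.converged = False
    state.warning = None
    while steps < max_steps:
        fmax = float(np.max(np.linalg.norm(F, axis=1))) if len(F) else 0.0
        if fmax < tol:
            state.converged = True
            break
        if steps >= stall_window and (
            trace[-stall_window - 1] - E <= stall_rtol * (1.0 + abs(E))
        ):
            state.converged = True
            break
        trial = pts + dt * F
        try:
            E2, F2 = engine(trial)
            ok = E2 <= E
        except (QhullError, InvalidStateError, np.linalg.LinAlgError,
                DegenerateGeometryError):
            ok = False
        if ok:
            pts, E, F = trial, E2, F2
            trace.append(E)
            dt = min(dt * 1.2, dt_max)
            steps += 1
        else:
            dt *= 0.5
            if dt < 1e-14:
                state.warning = "step size underflow before convergence"
                break
    else:
        state.warning = f"not converged after {max_steps} steps (tol={tol})"
    pts[fixed] = fixed_pts  # fixed centers bitwise unchanged
    state.centers.positions = pts
    state.invalidate()
    state.step_count += steps
    state.energy = E
    state.energy_trace.extend(trace)
    return state


# ---------------------------------------------------------------------------
# confinement protocol
# ---------------------------------------------------------------------------


def initialize_pattern(
    spec: ConfinementSpec,
    seed: int = 0,
    n_per_side: int = tess.DEFAULT_N_PER_SIDE,
    domain_side: float = tess.DEFAULT_DOMAIN_SIDE,
    jitter: float = tess.DEFAULT_JITTER,
    params: MechanicsParams | None = None,
    dt: float = 0.02,
    tol: float = 1e-4,
    max_steps: int = 12_000,
    reference_areas: str = "seeded",
) -> SimulationState:
    """Seed, demarcate and round up the micropattern; fix its boundary.

    Seeds the square domain, demarcates the pattern by thresholding
    center-to-pattern-center distance, relaxes the initialization energy
    (uniform stiffness, rim tension, global area penalty) to round the
    border, then fixes the exterior centers and the outermost demarcated
    ring (the boundary cells); the remaining demarcated cells stay movable.

    ``reference_areas`` selects the stress-free reference A0 of each cell:
    ``"seeded"`` (default) keeps the pre-relaxation Voronoi areas, which
    makes the rounded-up state an equilibrium of the main-phase energy at
    g = rho = 1 (the null condition stays put); ``"relaxed"`` resets A0 to
    the post-initialization areas instead, which zeroes the elastic term at
    the start of the main phase but lets the unbalanced junction tension
    re-condense the pattern even without prestretch.
    """
    params = params if params is not None else MechanicsParams()
    centers = generate_seed_points(n_per_side, domain_side, jitter, seed)
    demarc = spec.demarcate(centers.positions)
    if int(demarc.sum()) < 20:
        raise InvalidConfigurationError(
            f"demarcation captured only {int(demarc.sum())} cells"
        )
    # the energy only involves demarcated cells and their immediate
    # surroundings; drop centers far outside the pattern (they are fixed and
    # mechanically irrelevant) to keep the per-step tessellation small
    spacing = domain_side / n_per_side
    r = np.linalg.norm(centers.positions - np.asarray(spec.center), axis=1)
    keep = r <= spec.outer_radius + 2.5 * spacing
    centers = CellCenters(
        ids=centers.ids[keep],
        positions=centers.positions[keep],
        mobile=centers.mobile[keep],
        cell_class=centers.cell_class[keep],
    )
    demarc = spec.demarcate(centers.positions)
    cls = np.full(len(centers), EXTERIOR, dtype=object)
    cls[demarc] = INTERIOR
    centers.cell_class = cls

    state = SimulationState(
        centers=centers, params=params, pattern=spec, phase=PHASE_INIT
    )
    t0 = state.tessellation
    # stress-free reference: the seeded Voronoi areas
    A0 = np.where(t0.bounded, t0.areas, np.nan)
    state.params = replace(
        params, A0_per_cell=A0, A0_total=float(np.nansum(A0[demarc]))
    )

    # only the demarcated cells move while the border is rounded; the fixed
    # surroundings pin the tiled pattern area through the Voronoi partition
    centers.mobile = demarc & t0.bounded

    relax(state, PHASE_INIT, dt=dt, tol=tol, max_steps=max_steps)
    if state.warning:
        warnings.warn(f"initialization: {state.warning}", stacklevel=2)

    # freeze: stress-free reference areas, boundary ring detection
    t1 = state.tessellation
    if reference_areas == "relaxed":
        A0 = np.where(demarc, t1.areas, np.nan)
    elif reference_areas == "seeded":
        A0 = state.params.A0_per_cell
    else:
        raise InvalidConfigurationError(
            f"reference_areas must be 'seeded' or 'relaxed', got {reference_areas!r}"
        )
    boundary = np.zeros(len(centers), dtype=bool)
    for i in np.where(demarc)[0]:
        if any(not demarc[j] for j in t1.neighbors(int(i))):
            boundary[i] = True
    cls = np.full(len(centers), EXTERIOR, dtype=object)
    cls[demarc] = INTERIOR
    cls[boundary] = BOUNDARY
    centers.cell_class = cls
    centers.mobile = demarc & ~boundary
    state.params = replace(
        state.params, A0_per_cell=A0, A0_total=float(np.nansum(A0[demarc]))
    )
    state.phase = PHASE_MAIN
    state.converged = False
    state.invalidate()
    return state


def run_equilibrium(
    spec: ConfinementSpec,
    g: float = 1.0,
    rho: float = 1.0,
    rho_g: float = 1.0,
    seed: int = 0,
    lam: float = 15.0,
    dt: float = 0.02,
    tol: float = 1e-4,
    max_steps: int = 16_000,
    stall_rtol: float = 1e-10,
    init_kwargs: dict | None = None,
) -> SimulationState:
    """Initialization followed by main-phase relaxation at (g, rho, rho_g)."""
    state = initialize_pattern(spec, seed=seed, **(init_kwargs or {}))
    state.params = replace(
        state.params, g=g, rho=rho, rho_g=rho_g, lam=lam
    )
    state.energy_trace = []
    relax(
        state, PHASE_MAIN, dt=dt, tol=tol, max_steps=max_steps,
        stall_rtol=stall_rtol,
    )
    return state
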