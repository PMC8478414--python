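import copy
from dataclasses import replace

import numpy as np
import pytest

import voromech as vm
from voromech import mechanics as mech
from voromech.errors import InvalidConfigurationError
from voromech.mechanics import (
    PHASE_INIT,
    PHASE_MAIN,
    ConfinementSpec,
    MechanicsParams,
    cell_energy,
    forces,
    initialize_pattern,
    relax,
    run_equilibrium,
    total_energy,
)
from voromech.tessellation import BOUNDARY, EXTERIOR, INTERIOR


def smooth_len(lengths, eps):
    lengths = np.asarray(lengths, dtype=float)
    return float(np.sum(np.sqrt(lengths**2 + eps**2) - eps))


class TestMechanicsParams:
    @pytest.mark.parametrize("field,value", [("g", 0.0), ("rho", 1.5), ("rho_g", -0.1)])
    def test_differentials_bounded(self, field, value):
        with pytest.raises(InvalidConfigurationError):
            MechanicsParams(**{field: value})

    def test_effective_parameters_by_class(self):
        p = MechanicsParams(K_interior=2.0, rho=0.4, g=0.5, rho_g=0.5)
        cls = np.array([INTERIOR, BOUNDARY, EXTERIOR], dtype=object)
        K, g = p.effective(cls)
        assert np.allclose(K[:2], [2.0, 0.8])
        assert np.allclose(g[:2], [0.5, 0.25])


class TestCellEnergy:
    def test_relaxed_cell_zero(self):
        p = MechanicsParams(lam=0.0)
        cell = {"area": 1.0, "A0": 1.0, "cell_class": INTERIOR}
        assert cell_energy(cell, p, PHASE_MAIN) == 0.0

    def test_direct_formula_value(self):
        # K=1, g=0.5, A0=2 (gA0=1), A=1.5 -> 0.5 * 1 * (0.5)^2 = 0.125
        p = MechanicsParams(g=0.5, lam=0.0)
        cell = {"area": 1.5, "A0": 2.0, "cell_class": INTERIOR}
        assert np.isclose(cell_energy(cell, p, PHASE_MAIN), 0.125)

    def test_hexagonal_cell_term_by_term(self):
        p = MechanicsParams(lam=15.0, g=1.0)
        lengths = np.full(6, 0.7)
        cell = {
            "area": 1.2,
            "A0": 1.0,
            "cell_class": INTERIOR,
            "junction_lengths": lengths,
        }
        expected = 0.5 * 1.0 * 1.0 * (1.2 - 1.0) ** 2 + 15.0 * smooth_len(
            lengths, p.tension_eps
        )
        assert np.isclose(cell_energy(cell, p, PHASE_MAIN), expected, rtol=1e-12)

    def test_boundary_cell_uses_differentials(self):
        p = MechanicsParams(g=0.5, rho=0.4, rho_g=0.5, lam=0.0)
        cell = {"area": 0.125, "A0": 1.0, "cell_class": BOUNDARY}
        # g_eff = 0.25, K_eff = 0.4; A = 0.5 gA0 -> 0.5*0.4*0.25*(0.5)^2
        assert np.isclose(cell_energy(cell, p, PHASE_MAIN), 0.5 * 0.4 * 0.25 * 0.25)


class TestTotalEnergyAndForces:
    def test_total_energy_matches_term_oracle(self, small_confined_state):
        """Brute-force recomputation of every term from the tessellation."""
        state = small_confined_state
        p = state.params
        t = state.tessellation
        demarc = state.demarcated
        for phase in (PHASE_INIT, PHASE_MAIN):
            elastic = 0.0
            tension = 0.0
            in_energy = t.bounded if phase == PHASE_INIT else demarc
            for i in np.where(in_energy)[0]:
                A = t.areas[i]
                A0 = p.A0_per_cell[i]
                elastic += 0.5 * A0 * (A / A0 - 1.0) ** 2
            for j in t.junctions:
                di, dj = demarc[j.cell_i], demarc[j.cell_j]
                lam_tot = 2.0 * p.lam if (di and dj) else 0.0
                if phase == PHASE_INIT and (di != dj):
                    lam_tot += p.lambda_out
                tension += lam_tot * smooth_len([j.length], p.tension_eps)
            expected = elastic + tension
            if phase == PHASE_INIT:
                A_tot = float(np.sum(t.areas[demarc]))
                expected += 0.5 * p.k_b * p.A0_total * (A_tot / p.A0_total - 1) ** 2
            pos = state.centers.positions
            for j in t.junctions:
                d = np.linalg.norm(pos[j.cell_i] - pos[j.cell_j])
                if d < p.core_radius:
                    expected += 0.5 * p.core_stiffness * (p.core_radius - d) ** 2
            assert np.isclose(total_energy(state, phase), expected, rtol=1e-10)

    @pytest.mark.parametrize("phase", [PHASE_INIT, PHASE_MAIN])
    def test_forces_match_central_differences(self, small_confined_state, phase):
        """Analytic chain-rule forces vs central finite differences."""
        state = small_confined_state
        engine = mech._Engine(state, phase)
        pts = state.centers.positions
        E0, F = engine(pts)
        diam = 2.0 * np.sqrt(np.nanmean(state.params.A0_per_cell) / np.pi)
        h = 1e-6 * diam
        movable = np.where(state.centers.mobile)[0]
        for i in movable[:: max(1, len(movable) // 15)]:
            for d in range(2):
                p = pts.copy()
                p[i, d] += h
                Ep, _ = engine(p)
                p[i, d] -= 2 * h
                Em, _ = engine(p)
                fd = -(Ep - Em) / (2 * h)
                if abs(F[i, d]) > 1e-8:
                    assert abs(fd - F[i, d]) / abs(F[i, d]) < 1e-5

    def test_fixed_centers_get_zero_force(self, small_confined_state):
        state = small_confined_state
        F = forces(state, PHASE_MAIN)
        assert np.all(F[~state.centers.mobile] == 0.0)

    def test_hexagonal_symmetry_zero_force_on_center(self):
        """Perfect hexagonal packing at the stress-free area: the central
        cell feels no net force."""
        pts = []
        for row in range(-4, 5):
            for col in range(-4, 5):
                pts.append((col + 0.5 * (row % 2), row * np.sqrt(3) / 2))
        pts = np.array(pts, dtype=float) * 100.0
        n = len(pts)
        centers = vm.CellCenters(
            np.arange(n), pts, np.ones(n, bool), np.full(n, INTERIOR, dtype=object)
        )
        spec = ConfinementSpec(outer_radius=1000.0, center=(0.0, 0.0))
        state = vm.SimulationState(
            centers, MechanicsParams(lam=5.0, tension_eps=1.0), spec
        )
        t = state.tessellation
        state.params = replace(
            state.params,
            A0_per_cell=np.where(t.bounded, t.areas, np.nan),
            A0_total=float(np.nansum(t.areas[t.bounded])),
        )
        centers.cell_class[~t.bounded] = EXTERIOR
        centers.mobile = t.bounded.copy()
        F = forces(state, PHASE_MAIN)
        mid = int(np.argmin(np.linalg.norm(pts, axis=1)))
        assert np.linalg.norm(F[mid]) < 1e-8


class TestScalingCovariance:
    def test_energy_and_forces_scale_with_length(self, small_confined_state):
        """Scaling lengths by s (and A0 by s^2, tension-like parameters by
        s) scales the energy by s^2 and forces by s."""
        state = small_confined_state
        s = 1.7
        scaled = copy.deepcopy(state)
        scaled.centers.positions = scaled.centers.positions * s
        scaled.pattern = ConfinementSpec(
            shape=state.pattern.shape,
            outer_radius=state.pattern.outer_radius * s,
            center=tuple(np.asarray(state.pattern.center) * s),
        )
        p = state.params
        scaled.params = replace(
            p,
            lam=p.lam * s,
            lambda_out=p.lambda_out * s,
            tension_eps=p.tension_eps * s,
            core_radius=p.core_radius * s,
            core_stiffness=p.core_stiffness,
            A0_per_cell=p.A0_per_cell * s**2,
            A0_total=p.A0_total * s**2,
        )
        scaled.invalidate()
        for phase in (PHASE_INIT, PHASE_MAIN):
            E1 = total_energy(state, phase)
            E2 = total_energy(scaled, phase)
            assert np.isclose(E2, s**2 * E1, rtol=1e-9)
            F1 = forces(state, phase)
            F2 = forces(scaled, phase)
            scale = np.abs(F1).max()
            assert np.allclose(F2, s * F1, rtol=1e-8, atol=1e-9 * s * scale)


class TestRelax:
    def test_already_relaxed_returns_immediately(self, small_confined_state):
        state = copy.deepcopy(small_confined_state)
        state.params = replace(state.params, lam=0.0, lambda_out=0.0)
        before = state.centers.positions.copy()
        relax(state, PHASE_MAIN, dt=0.02, tol=1e-6, max_steps=100)
        assert state.converged
        assert state.step_count == 0
        assert np.array_equal(state.centers.positions, before)

    def test_displaced_center_relaxes_back(self, small_confined_state):
        state = copy.deepcopy(small_confined_state)
        state.params = replace(state.params, lam=0.0, lambda_out=0.0)
        movable = np.where(state.centers.mobile)[0]
        i = movable[len(movable) // 2]
        state.centers.positions[i] += np.array([20.0, -12.0])
        state.invalidate()
        E0 = total_energy(state, PHASE_MAIN)
        relax(state, PHASE_MAIN, dt=0.02, tol=1e-6, max_steps=5000)
        assert state.energy < E0
        assert state.converged

    def test_energy_trace_monotone_and_fixed_centers_unchanged(
        self, small_confined_state
    ):
        state = copy.deepcopy(small_confined_state)
        fixed = ~state.centers.mobile
        frozen = state.centers.positions[fixed].copy()
        relax(state, PHASE_INIT, dt=0.02, tol=1e-4, max_steps=800)
        trace = np.asarray(state.energy_trace)
        assert len(trace) > 2
        assert np.all(np.diff(trace) <= 0)
        assert np.array_equal(state.centers.positions[fixed], frozen)

    def test_invalid_dt(self, small_confined_state):
        with pytest.raises(InvalidConfigurationError):
            relax(copy.deepcopy(small_confined_state), PHASE_MAIN, dt=0.0)


class TestInitializePattern:
    def test_circle_demarcation_and_classes(self):
        state = initialize_pattern(ConfinementSpec(), seed=1)
        cls = state.centers.cell_class
        n_boundary = int((cls == BOUNDARY).sum())
        n_demarc = int(state.demarcated.sum())
        assert 120 <= n_demarc <= 124
        assert 30 <= n_boundary <= 50
        # boundary and exterior fixed, interior movable
        assert not state.centers.mobile[cls == BOUNDARY].any()
        assert not state.centers.mobile[cls == EXTERIOR].any()
        assert state.centers.mobile[cls == INTERIOR].all()

    def test_annulus_has_two_fixed_rings(self):
        spec = ConfinementSpec(
            shape="annulus",
            outer_radius=mech.DEFAULT_PATTERN_RADIUS,
            inner_radius=mech.DEFAULT_PATTERN_RADIUS / 2,
        )
        state = initialize_pattern(spec, seed=2)
        cls = state.centers.cell_class
        pos = state.centers.positions
        r = np.linalg.norm(pos - np.asarray(spec.center), axis=1)
        hole = (cls == EXTERIOR) & (r < spec.inner_radius)
        assert hole.sum() > 5  # cells in the hole are exterior
        assert not state.centers.mobile[hole].any()
        # boundary cells hug both rims
        rb = r[cls == BOUNDARY]
        assert (rb < spec.inner_radius + 60).any()
        assert (rb > spec.outer_radius - 60).any()

    def test_too_small_pattern_raises(self):
        with pytest.raises(InvalidConfigurationError):
            initialize_pattern(ConfinementSpec(outer_radius=40.0), seed=0)

    def test_zero_tension_initialization_is_equilibrium(self):
        """Zero-mode: with no tension the seeded state is stress free and
        initialization must not move anything appreciably."""
        params = MechanicsParams(lam=0.0, lambda_out=0.0)
        state = initialize_pattern(ConfinementSpec(), seed=3, params=params)
        F = forces(state, PHASE_MAIN)
        assert np.max(np.linalg.norm(F, axis=1)) < 1e-6


class TestRunEquilibrium:
    def test_no_driving_terms_equilibrium_equals_initialization(self):
        params = MechanicsParams(lam=0.0, lambda_out=0.0)
        init = initialize_pattern(ConfinementSpec(), seed=4, params=params)
        final = run_equilibrium(
            ConfinementSpec(),
            g=1.0,
            rho=1.0,
            rho_g=1.0,
            seed=4,
            lam=0.0,
            init_kwargs={"params": params},
        )
        assert np.allclose(
            init.centers.positions, final.centers.positions, atol=1e-9
        )

    def test_deterministic_given_seed(self):
        a = run_equilibrium(ConfinementSpec(), g=0.9, rho=0.9, seed=5, max_steps=600)
        b = run_equilibrium(ConfinementSpec(), g=0.9, rho=0.9, seed=5, max_steps=600)
        assert np.array_equal(a.centers.positions, b.centers.positions)
        assert a.energy == b.energy
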