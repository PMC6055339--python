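"""Trunk beam-element model: element correctness against closed forms,
structural properties of the assembled system, gravity loads, calibration."""

import numpy as np
import pytest

from gprspine.fem import (
    DEFAULT_MASS_FRACTIONS,
    FEMError,
    MechanismError,
    SegmentProperties,
    apply_gravity,
    assemble_chain,
    beam_element_stiffness,
    build_fem,
    calibrate_global_scale,
    solve,
    solve_system,
)
from gprspine.corrections import ManualCorrectionInput, simulate_manual_correction

from conftest import straight_spine

DEFAULT_ELEM = dict(k_ax=800.0, k_sh=150.0, k_lb=1.5e5, k_fe=1.5e5, k_tor=2.5e5)


def random_chain(rng, n_elem):
    """Random mildly-kinked chain with random per-element stiffnesses."""
    steps = rng.uniform([-6, -6, 24], [6, 6, 40], (n_elem, 3))
    points = np.vstack([[0.0, 0.0, 0.0], np.cumsum(steps, axis=0)])
    props = [
        dict(
            k_ax=float(rng.uniform(400, 1200)),
            k_sh=float(rng.uniform(80, 300)),
            k_lb=float(rng.uniform(0.8e5, 2.5e5)),
            k_fe=float(rng.uniform(0.8e5, 2.5e5)),
            k_tor=float(rng.uniform(1.5e5, 3.5e5)),
        )
        for _ in range(n_elem)
    ]
    return points, props


class TestElementClosedForms:
    def test_tip_loaded_cantilever_matches_closed_form(self):
        """Single vertical element, lateral tip force: Timoshenko cantilever
        deflection F L^3 / 3EI + F L / GAs with EI = k_lb L, GAs = k_sh L."""
        L, F = 35.0, 10.0
        pts = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, L]])
        K = assemble_chain(pts, [DEFAULT_ELEM])
        f = np.zeros(12)
        f[7] = F  # tip, +Y
        u, reactions, _ = solve_system(K, f, {i: 0.0 for i in range(6)})
        EI, GAs = DEFAULT_ELEM["k_lb"] * L, DEFAULT_ELEM["k_sh"] * L
        expected = F * L**3 / (3 * EI) + F * L / GAs
        assert u[7] == pytest.approx(expected, rel=1e-6)
        assert F + reactions[1] == pytest.approx(0.0, abs=1e-6)

    def test_three_element_cantilever_station_values(self):
        """Uniform 3-element vertical chain under a tip force matches the
        closed-form deflection and rotation at every interior node."""
        L_el, F = 30.0, 12.0
        n = 3
        L = n * L_el
        pts = np.array([[0.0, 0.0, i * L_el] for i in range(n + 1)])
        K = assemble_chain(pts, [DEFAULT_ELEM] * n)
        f = np.zeros(6 * (n + 1))
        f[6 * n + 1] = F
        u, _, _ = solve_system(K, f, {i: 0.0 for i in range(6)})
        EI, GAs = DEFAULT_ELEM["k_lb"] * L_el, DEFAULT_ELEM["k_sh"] * L_el
        for i in range(1, n + 1):
            a = i * L_el
            v = F * a**2 * (3 * L - a) / (6 * EI) + F * a / GAs
            # rotation about x from +Y deflection is negative of dv/dz slope
            th = F * a * (2 * L - a) / (2 * EI)
            assert u[6 * i + 1] == pytest.approx(v, rel=1e-9)
            assert u[6 * i + 3] == pytest.approx(-th, rel=1e-9)

    def test_axial_and_torsional_chains(self):
        L_el, n = 30.0, 4
        pts = np.array([[0.0, 0.0, i * L_el] for i in range(n + 1)])
        K = assemble_chain(pts, [DEFAULT_ELEM] * n)
        f = np.zeros(6 * (n + 1))
        f[6 * n + 2] = 100.0  # axial tip force
        u, _, _ = solve_system(K, f, {i: 0.0 for i in range(6)})
        assert u[6 * n + 2] == pytest.approx(n * 100.0 / DEFAULT_ELEM["k_ax"], rel=1e-9)
        f = np.zeros(6 * (n + 1))
        f[6 * n + 5] = 5e4  # torque about the chain axis
        u, _, _ = solve_system(K, f, {i: 0.0 for i in range(6)})
        assert u[6 * n + 5] == pytest.approx(n * 5e4 / DEFAULT_ELEM["k_tor"], rel=1e-9)

    def test_zero_length_element_rejected(self):
        with pytest.raises(FEMError, match="zero-length"):
            beam_element_stiffness(np.zeros(3), np.zeros(3), **DEFAULT_ELEM)


class TestStructuralProperties:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_randomized_chain_properties(self, seed):
        """Symmetry, rigid-mode nullity, equilibrium, linearity, superposition
        and reciprocity on random 2-4 element chains."""
        rng = np.random.default_rng(seed)
        n_elem = int(rng.integers(2, 5))
        points, props = random_chain(rng, n_elem)
        K = assemble_chain(points, props)
        n_dof = K.shape[0]
        scale = np.abs(K).max()

        assert np.abs(K - K.T).max() <= 1e-8 * scale

        # rigid translation and rotation live in the nullspace
        t = np.tile([1.0, -2.0, 0.5, 0, 0, 0], n_elem + 1)
        assert np.abs(K @ t).max() <= 1e-8 * scale
        w = rng.standard_normal(3)
        r = np.concatenate(
            [np.concatenate([np.cross(w, p - points[0]), w]) for p in points]
        )
        assert np.abs(K @ r).max() <= 1e-8 * scale * np.abs(r).max()

        fixed = {i: 0.0 for i in range(6)}
        f1 = np.zeros(n_dof)
        f1[6 * n_elem : 6 * n_elem + 3] = rng.uniform(-20, 20, 3)
        f2 = np.zeros(n_dof)
        f2[7] = 15.0
        u1, r1, _ = solve_system(K, f1, fixed)
        u2, _, _ = solve_system(K, f2, fixed)
        u12, _, _ = solve_system(K, f1 + f2, fixed)
        ua, _, _ = solve_system(K, 3.0 * f1, fixed)

        # equilibrium per translational axis
        for axis in range(3):
            total = f1[axis::6].sum() + r1[axis]
            assert total == pytest.approx(0.0, abs=1e-6)
        # linearity and superposition
        assert np.allclose(ua, 3.0 * u1, rtol=1e-9, atol=1e-12)
        assert np.allclose(u12, u1 + u2, rtol=1e-9, atol=1e-10)

        # reciprocity: cross deflections of unit loads at two free dofs
        i, j = 6 + 1, 6 * n_elem + 0
        ei = np.zeros(n_dof)
        ei[i] = 1.0
        ej = np.zeros(n_dof)
        ej[j] = 1.0
        ui, _, _ = solve_system(K, ei, fixed)
        uj, _, _ = solve_system(K, ej, fixed)
        assert ui[j] == pytest.approx(uj[i], rel=1e-9, abs=1e-15)

    def test_unconstrained_system_raises(self):
        pts = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 30.0]])
        K = assemble_chain(pts, [DEFAULT_ELEM])
        with pytest.raises(MechanismError):
            solve_system(K, np.zeros(12), {})


class TestTrunkModel:
    def test_structure_of_assembled_model(self, small_cohort):
        model = build_fem(small_cohort[0])
        assert model.K.shape == (108, 108)
        assert len(model.constraints) == 6  # S1 fully fixed
        res = solve(model)
        assert np.abs(res.u).max() == 0.0  # no loads -> no motion

    def test_global_scale_doubles_stiffness(self, small_cohort):
        m1 = build_fem(small_cohort[0], SegmentProperties())
        m2 = build_fem(small_cohort[0], SegmentProperties(global_scale=2.0))
        assert np.allclose(m2.K, 2.0 * m1.K)

    def test_stiffer_model_moves_less(self, small_cohort):
        loads = [("T8", 1, 20.0)]
        mags = []
        for s in (0.5, 1.0, 2.0):
            model = build_fem(small_cohort[0], SegmentProperties().with_scale(s))
            mags.append(np.abs(solve(model, loads=loads).u).max())
        assert mags[0] > mags[1] > mags[2]

    def test_gravity_loads(self, small_cohort):
        model = build_fem(small_cohort[0])
        assert apply_gravity(model, 0.0) == []
        loads = apply_gravity(model, 50.0)
        total = sum(v for _, comp, v in loads if comp == 2)
        assert total == pytest.approx(-0.45 * 50.0 * 9.81)
        assert sum(DEFAULT_MASS_FRACTIONS.values()) == pytest.approx(0.45)
        with pytest.raises(FEMError, match="negative"):
            apply_gravity(model, 50.0, {"T8": -0.1})

    def test_gravity_on_straight_spine_is_pure_axial(self):
        model = build_fem(straight_spine())
        res = solve(model, loads=apply_gravity(model, 50.0))
        assert np.abs(res.u[:, 0:2]).max() < 1e-9
        assert res.u[1:, 2].max() < 0.0  # everything settles downward


class TestCalibration:
    def test_fixed_point_returns_unit_scale(self, small_cohort):
        from gprspine.corrections import manual_correction_parts

        base = SegmentProperties().with_scale(1.0)
        parts = [manual_correction_parts(build_fem(s, base), 31.0) for s in small_cohort]
        target = float(np.mean([p.reduction_pct_at_scale(1.0) for p in parts]))
        s = calibrate_global_scale(small_cohort, target, 31.0)
        assert s == pytest.approx(1.0, abs=0.01)

    def test_larger_target_gives_softer_model(self, small_cohort):
        s_small = calibrate_global_scale(small_cohort, 15.0, 31.0)
        s_large = calibrate_global_scale(small_cohort, 30.0, 31.0)
        assert s_large < s_small

    def test_calibrated_model_hits_target_mean(self, small_cohort):
        target = 26.0
        s = calibrate_global_scale(small_cohort, target, 31.0)
        assert 0.05 <= s <= 20.0
        props = SegmentProperties().with_scale(s)
        reductions = [
            simulate_manual_correction(
                build_fem(sp, props), ManualCorrectionInput(force=31.0)
            ).reduction_pct
            for sp in small_cohort
        ]
        assert abs(np.mean(reductions) - target) <= 0.5

    def test_unreachable_target_raises(self, small_cohort):
        with pytest.raises(FEMError, match="unreachable|exceeded"):
            calibrate_global_scale(small_cohort, 400.0, 31.0)
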