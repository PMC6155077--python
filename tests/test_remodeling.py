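import numpy as np
import pytest

from hosim.fe_solver import LoadCase, Support
from hosim.geometry import element_geometry, mirror_mesh
from hosim.materials import DENSITY_RANGES, MaterialParams, TissueClass
from hosim.remodeling import (
    CellFieldMode,
    RemodelParams,
    beta_field,
    mesenchymal_field,
    run_simulation,
    sensor_weights,
    stimulus_field,
    stimulus_field_bruteforce,
    update_density,
)
from hosim.scenarios import Schedule, make_schedule


class TestMesenchymalField:
    def test_linear_distal_field(self, mini_mesh):
        """1 at the wound, 0.01 at the farthest element, 0.505 half-way."""
        cf = mesenchymal_field(mini_mesh)
        cent, _ = element_geometry(mini_mesh)
        d = np.linalg.norm(cent - cf.wound_point, axis=1)
        assert cf.rho_msc[np.argmin(d)] > 0.95
        assert cf.rho_msc[np.argmax(d)] == pytest.approx(0.01, abs=1e-12)
        mid = np.argmin(np.abs(d - d.max() / 2.0))
        expected = 1.0 + (0.01 - 1.0) * d[mid] / d.max()
        assert cf.rho_msc[mid] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.505, abs=0.02)

    def test_radial_mode_requires_inside_point(self, mini_mesh):
        with pytest.raises(ValueError, match="outside"):
            mesenchymal_field(mini_mesh, (1e5, 1e5), CellFieldMode.RADIAL_FROM_POINT)

    def test_bounds(self, mini_mesh):
        cf = mesenchymal_field(mini_mesh)
        assert cf.rho_msc.min() >= 0.01 and cf.rho_msc.max() <= 1.0


class TestBeta:
    def test_p_one_gives_one(self):
        msc = np.linspace(0.01, 1.0, 7)
        assert beta_field(np.ones(7), msc) == pytest.approx(np.ones(7), abs=1e-15)

    def test_soft_callus_values(self):
        assert beta_field(np.array([0.6]), np.array([1.0]))[0] == pytest.approx(
            0.6 ** (2.0 / 3.0), abs=1e-12
        )
        far = beta_field(np.array([0.6]), np.array([0.01]))[0]
        assert far == pytest.approx(0.6 ** (100.0 / 1.5), rel=1e-9)
        assert far < 1e-14

    def test_product_exponent_alternative(self):
        got = beta_field(np.array([0.6]), np.array([0.3]), exponent="product")
        assert got[0] == pytest.approx(0.6 ** 0.2, abs=1e-12)

    def test_domain_validation(self):
        with pytest.raises(ValueError):
            beta_field(np.array([0.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            beta_field(np.array([0.5]), np.array([0.001]))


class TestStimulus:
    def test_single_element_at_equilibrium(self):
        p = RemodelParams()
        k = p.k[TissueClass.SOFT]
        phi = stimulus_field_bruteforce(
            np.zeros((1, 2)), np.array([k]), np.array([1.0]),
            np.array([int(TissueClass.SOFT)]), p,
        )
        assert phi[0] == pytest.approx(0.0, abs=1e-15)

    def test_lazy_zone_gates_femur(self):
        """A femoral element within ±10% of K produces zero stimulus."""
        p = RemodelParams()
        k = p.k[TissueClass.CORTICAL]
        phi = stimulus_field_bruteforce(
            np.zeros((1, 2)), np.array([1.05 * k * 1.7]), np.array([1.7]),
            np.array([int(TissueClass.CORTICAL)]), p,
        )
        assert phi[0] == 0.0
        phi = stimulus_field_bruteforce(
            np.zeros((1, 2)), np.array([1.2 * k * 1.7]), np.array([1.7]),
            np.array([int(TissueClass.CORTICAL)]), p,
        )
        assert phi[0] == pytest.approx(0.2 * k, rel=1e-9)

    def test_no_lazy_zone_for_soft_and_ho(self):
        p = RemodelParams()
        for cls in (TissueClass.SOFT, TissueClass.HO):
            k = p.k[cls]
            phi = stimulus_field_bruteforce(
                np.zeros((1, 2)), np.array([1.05 * k]), np.array([1.0]),
                np.array([int(cls)]), p,
            )
            assert phi[0] == pytest.approx(0.05 * k, rel=1e-9)

    def test_two_element_hand_example(self):
        """Two soft elements one influence-distance apart: each sees its
        own error plus e⁻¹ of the neighbour's."""
        p = RemodelParams()
        k = p.k[TissueClass.SOFT]
        e1, e2 = 0.01, 0.02
        cent = np.array([[0.0, 0.0], [p.d_mm, 0.0]])
        sed = np.array([k + e1, k + e2])
        tissue = np.full(2, int(TissueClass.SOFT))
        phi = stimulus_field_bruteforce(cent, sed, np.ones(2), tissue, p)
        assert phi[0] == pytest.approx(e1 + e2 * np.exp(-1.0), rel=1e-12)
        assert phi[1] == pytest.approx(e2 + e1 * np.exp(-1.0), rel=1e-12)

    def test_zero_density_error(self):
        p = RemodelParams()
        with pytest.raises(ValueError):
            stimulus_field_bruteforce(
                np.zeros((1, 2)), np.array([0.1]), np.array([0.0]),
                np.array([int(TissueClass.SOFT)]), p,
            )

    def test_cutoff_matches_bruteforce(self, model1_mesh):
        """Cutoff-accelerated stimulus equals the all-pairs oracle to
        1e-6 relative with the 20·D cutoff."""
        rng = np.random.default_rng(42)
        p = RemodelParams()
        eligible = model1_mesh.region_mask(
            TissueClass.CORTICAL, TissueClass.TRABECULAR, TissueClass.SOFT
        )
        cent, _ = element_geometry(model1_mesh)
        cent = cent[eligible]
        n = len(cent)
        tissue = model1_mesh.element_region[eligible]
        rho = rng.uniform(0.5, 1.5, n)
        sed = rng.uniform(0.0, 0.01, n)
        ref = stimulus_field_bruteforce(cent, sed, rho, tissue, p)
        w = sensor_weights(cent, p)
        got = stimulus_field(cent, sed, rho, tissue, p, w)
        scale = np.abs(ref).max()
        assert np.abs(got - ref).max() < 1e-6 * scale


class TestUpdateDensity:
    def test_basic_arithmetic(self):
        p = RemodelParams()
        rho = np.array([0.95])
        tissue = np.array([int(TissueClass.SOFT)])
        rho2, t2, dm = update_density(
            rho, tissue, np.array([0.01]), np.array([0.5]), p, np.array([True])
        )
        assert rho2[0] == pytest.approx(0.955, abs=1e-12)
        assert dm == pytest.approx(0.005, abs=1e-12)

    def test_soft_transition_keeps_density(self):
        p = RemodelParams()
        rho = np.array([1.1])
        tissue = np.array([int(TissueClass.SOFT)])
        rho2, t2, _ = update_density(
            rho, tissue, np.array([0.15]), np.array([1.0]), p, np.array([True])
        )
        assert t2[0] == int(TissueClass.HO)
        assert rho2[0] == pytest.approx(1.25, abs=1e-12)

    def test_skin_never_changes(self):
        p = RemodelParams()
        rho = np.array([0.95, 0.95])
        tissue = np.array([int(TissueClass.SKIN), int(TissueClass.SOFT)])
        eligible = tissue == int(TissueClass.SOFT)
        rho2, t2, _ = update_density(
            rho, tissue, np.array([0.5]), np.array([1.0]), p, eligible
        )
        assert rho2[0] == 0.95
        assert t2[0] == int(TissueClass.SKIN)

    def test_clamping_to_class_ranges(self):
        p = RemodelParams()
        rho = np.array([2.0, 0.2])
        tissue = np.array([int(TissueClass.HO), int(TissueClass.TRABECULAR)])
        eligible = np.ones(2, dtype=bool)
        rho2, _, _ = update_density(
            rho, tissue, np.array([10.0, -10.0]), np.ones(2), p, eligible
        )
        assert rho2[0] == pytest.approx(2.2)
        assert rho2[1] == pytest.approx(0.1, abs=1e-6)


def zero_load_schedule(mesh, n):
    lc = LoadCase(supports=[Support(mesh.node_sets["socket_base"], 0.0, 0.0)], name="none")
    return Schedule("zero", [(lc, 1, n)])


class TestRunSimulation:
    def test_zero_load_monotone_resorption(self, mini_mesh):
        """With no load the stimulus is negative everywhere, so all
        densities fall monotonically toward their range floors."""
        sched = zero_load_schedule(mini_mesh, 40)
        params = RemodelParams(max_iterations=40, convergence_threshold=1e-12)
        prev = None
        state = run_simulation(mini_mesh, sched, params)
        eligible = state.eligible_mask()
        lo_cort = DENSITY_RANGES[TissueClass.CORTICAL][0]
        cort = state.tissue == int(TissueClass.CORTICAL)
        assert state.rho[cort] == pytest.approx(lo_cort, abs=1e-6)
        soft = state.tissue == int(TissueClass.SOFT)
        # β collapses far from the wound, so distant soft elements barely
        # move; near the wound the decrease is clear
        assert np.all(state.rho[soft] <= 0.95 + 1e-12)
        assert state.rho[soft].min() < 0.94
        assert np.all(np.diff(state.mean_drho_history[-10:]) <= 1e-12)

    def test_equilibrium_is_stationary(self):
        """A state whose every element sits inside its lazy zone (or at
        exactly K) does not move: fixed point of the density update."""
        p = RemodelParams()
        n = 5
        cent = np.column_stack([np.linspace(0, 20, n), np.zeros(n)])
        tissue = np.full(n, int(TissueClass.CORTICAL))
        rho = np.full(n, 1.7)
        sed = rho * p.k[TissueClass.CORTICAL]  # exactly at equilibrium
        phi = stimulus_field_bruteforce(cent, sed, rho, tissue, p)
        assert np.all(phi == 0.0)
        rho2, _, dm = update_density(rho, tissue, phi, np.ones(n), p, np.ones(n, bool))
        assert np.array_equal(rho2, rho)
        assert dm == 0.0

    def test_determinism(self, mini_mesh):
        sched = make_schedule("upright", mini_mesh, max_iterations=15)
        p = RemodelParams(max_iterations=15, convergence_threshold=1e-12)
        s1 = run_simulation(mini_mesh, sched, p)
        s2 = run_simulation(mini_mesh, sched, p)
        assert np.array_equal(s1.rho, s2.rho)
        assert s1.mean_drho_history == s2.mean_drho_history

    def test_range_safety_and_one_way_transitions(self, mini_mesh):
        sched = make_schedule("upright", mini_mesh, max_iterations=120)
        p = RemodelParams(max_iterations=120, convergence_threshold=1e-12)
        state = run_simulation(mini_mesh, sched, p)
        for cls in (TissueClass.CORTICAL, TissueClass.TRABECULAR, TissueClass.HO):
            m = state.tissue == int(cls)
            if m.any():
                lo, hi = DENSITY_RANGES[cls]
                assert np.all(state.rho[m] >= lo) and np.all(state.rho[m] <= hi)
        # SKIN/LINER/SOCKET untouched
        fixed = ~state.eligible_mask()
        assert np.array_equal(state.tissue[fixed], mini_mesh.element_region[fixed])

    def test_monotone_load_response(self, mini_mesh):
        """1.5× upright load produces at least as much HO as 1× on the
        shipped fixture."""
        from hosim.fe_solver import build_load_case

        results = []
        for scale in (1.0, 1.5):
            lc = build_load_case(mini_mesh)
            lc.nodal_forces = [(n, f * scale) for n, f in lc.nodal_forces]
            sched = Schedule("scaled", [(lc, 1, 150)])
            p = RemodelParams(max_iterations=150, convergence_threshold=1e-12)
            state = run_simulation(mini_mesh, sched, p)
            results.append(state.ho_area_history[-1])
        assert results[1] >= results[0]

    def test_mirror_equivariance(self, mini_mesh):
        """Mirrored mesh with mirrored loads remodels to the mirrored
        density field."""
        from hosim.fe_solver import build_load_case

        lc = build_load_case(mini_mesh)
        sched = Schedule("up", [(lc, 1, 10)])
        p = RemodelParams(max_iterations=10, convergence_threshold=1e-12)
        s1 = run_simulation(mini_mesh, sched, p)

        mm = mirror_mesh(mini_mesh)
        lc_m = LoadCase(
            nodal_forces=[(n, f * np.array([-1.0, 1.0])) for n, f in lc.nodal_forces],
            supports=lc.supports,
        )
        sched_m = Schedule("up_m", [(lc_m, 1, 10)])
        s2 = run_simulation(mm, sched_m, p)
        assert np.allclose(s2.rho, s1.rho, atol=5e-6)
        assert np.array_equal(s2.tissue, s1.tissue)
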