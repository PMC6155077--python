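import numpy as np
import pytest

from hosim.app import square_mesh, strip_mesh
from hosim.fe_solver import (
    THICKNESS_MM,
    LoadCase,
    SolverError,
    Support,
    assemble_and_solve,
    build_load_case,
    equivalent_strain,
    rotate,
    solve_with_soft_tissue_iteration,
)
from hosim.geometry import boundary_edge_array, mirror_mesh
from hosim.materials import TissueClass, soft_tissue_modulus
from hosim.scenarios import make_schedule


def boundary_supports(mesh, u_fn):
    nodes = np.unique(boundary_edge_array(mesh.triangles))
    return [Support(np.array([n]), *u_fn(mesh.nodes[n])) for n in nodes]


class TestLinearSolve:
    def test_uniaxial_traction_closed_form(self):
        """Unit square of 2 CSTs under 1 kPa traction: uniform stress,
        SED = σ²/2E."""
        mesh = square_mesh(1, 1.0)
        e = np.full(2, 1.0)  # 1 MPa
        nu = np.zeros(2)
        sigma = 1e-3  # 1 kPa in MPa
        f_total = sigma * 1.0 * THICKNESS_MM
        lc = LoadCase(
            nodal_forces=[(np.array([1, 3]), np.array([f_total, 0.0]))],
            supports=[
                Support(np.array([0]), 0.0, 0.0),
                Support(np.array([2]), 0.0, None),
            ],
        )
        res = assemble_and_solve(mesh, e, nu, lc)
        assert res.stress[:, 0] == pytest.approx([sigma, sigma], rel=1e-9)
        assert res.sed == pytest.approx(sigma**2 / 2.0, rel=1e-9)

    def test_patch_reproduces_uniform_strain_exactly(self, patch):
        """CST is exact for linear displacement fields."""
        exx, eyy, gxy = 0.003, -0.001, 0.002

        def u(p):
            return (exx * p[0] + 0.5 * gxy * p[1], eyy * p[1] + 0.5 * gxy * p[0])

        lc = LoadCase(supports=boundary_supports(patch, u))
        res = assemble_and_solve(patch, np.full(patch.n_elements, 2.0), np.full(patch.n_elements, 0.3), lc)
        assert np.abs(res.strain - [exx, eyy, gxy]).max() < 1e-12

    def test_rigid_translation_zero_strain(self, patch):
        lc = LoadCase(supports=boundary_supports(patch, lambda p: (0.01, -0.02)))
        res = assemble_and_solve(
            patch, np.full(patch.n_elements, 2.0), np.full(patch.n_elements, 0.3), lc
        )
        assert np.abs(res.strain).max() < 1e-12
        assert np.abs(res.sed).max() < 1e-24

    def test_cantilever_tip_deflection(self, cantilever):
        """Euler–Bernoulli PL³/3EI within 10% on the refined strip (CST
        is overly stiff; the tolerance reflects that)."""
        L, h, E, P = 100.0, 10.0, 1000.0, 1.0
        left = np.where(cantilever.nodes[:, 0] < 1e-9)[0]
        tip = np.where(cantilever.nodes[:, 0] > L - 1e-9)[0]
        lc = LoadCase(
            nodal_forces=[(tip, np.array([0.0, -P]))],
            supports=[Support(left, 0.0, 0.0)],
        )
        res = assemble_and_solve(
            cantilever,
            np.full(cantilever.n_elements, E),
            np.zeros(cantilever.n_elements),
            lc,
        )
        inertia = THICKNESS_MM * h**3 / 12.0
        analytic = P * L**3 / (3.0 * E * inertia)
        mid = tip[np.argmin(np.abs(cantilever.nodes[tip, 1] - h / 2))]
        assert res.displacements[mid, 1] == pytest.approx(-analytic, rel=0.10)

    def test_equilibrium_every_solve(self, model1_mesh):
        """Σ reactions + Σ applied = 0 to 1e-6 relative."""
        from hosim.fe_solver import element_poisson, initial_element_moduli
        from hosim.materials import MaterialParams
        from hosim.remodeling import _initial_state

        mats = MaterialParams()
        st = _initial_state(model1_mesh, mats)
        nu = element_poisson(st.tissue, mats)
        lc = build_load_case(model1_mesh)
        res = assemble_and_solve(model1_mesh, st.e_elements, nu, lc)
        applied = res.applied.sum()
        scale = np.abs(res.applied).sum()
        assert abs(res.reactions.sum() + applied) < 1e-6 * scale
        assert np.all(res.sed >= 0.0)

    def test_insufficient_supports_error(self, patch):
        lc = LoadCase(supports=[Support(np.array([0]), 0.0, None)])
        with pytest.raises(SolverError, match="constrained"):
            assemble_and_solve(
                patch, np.full(patch.n_elements, 1.0), np.zeros(patch.n_elements), lc
            )

    def test_nonpositive_modulus_error(self, patch):
        lc = LoadCase(supports=[Support(np.array([0, 1]), 0.0, 0.0)])
        e = np.full(patch.n_elements, 1.0)
        e[0] = 0.0
        with pytest.raises(SolverError, match="modulus"):
            assemble_and_solve(patch, e, np.zeros(patch.n_elements), lc)

    def test_mirror_symmetry(self, model1_mesh):
        """Mirrored mesh + mirrored loads → mirrored displacements and
        identical SED per element pair."""
        from hosim.fe_solver import element_poisson
        from hosim.materials import MaterialParams
        from hosim.remodeling import _initial_state

        mats = MaterialParams()
        st = _initial_state(model1_mesh, mats)
        nu = element_poisson(st.tissue, mats)
        lc = build_load_case(model1_mesh)
        res = assemble_and_solve(model1_mesh, st.e_elements, nu, lc)

        mm = mirror_mesh(model1_mesh)
        lc_m = LoadCase(
            nodal_forces=[
                (nodes, total * np.array([-1.0, 1.0])) for nodes, total in lc.nodal_forces
            ],
            supports=lc.supports,
        )
        res_m = assemble_and_solve(mm, st.e_elements, nu, lc_m)
        assert np.allclose(
            res_m.displacements, res.displacements * [-1.0, 1.0], atol=1e-9
        )
        # sparse factorization pivot order differs on the mirrored mesh,
        # so agreement is to solver precision rather than bit-exact
        assert np.allclose(res_m.sed, res.sed, rtol=1e-6, atol=1e-18)


class TestSoftTissueIteration:
    def test_zero_load_floors_in_one_iteration(self, mini_mesh):
        from hosim.fe_solver import element_poisson
        from hosim.materials import MaterialParams
        from hosim.remodeling import _initial_state

        mats = MaterialParams()
        st = _initial_state(mini_mesh, mats)
        nu = element_poisson(st.tissue, mats)
        lc = LoadCase(supports=[Support(mini_mesh.node_sets["socket_base"], 0.0, 0.0)])
        soft = st.tissue == int(TissueClass.SOFT)
        res = solve_with_soft_tissue_iteration(
            mini_mesh, st.e_elements, nu, lc, soft
        )
        assert res.iterations == 1
        assert res.e_elements[soft] == pytest.approx(0.04e-3)
        assert np.abs(res.strain).max() == 0.0

    def test_uniform_strain_fixed_point(self):
        """A pure-shear patch with equivalent strain 0.1 converges to the
        secant modulus of the passive-muscle cubic at ε = 0.1."""
        mesh = square_mesh(3, 1.0)
        mesh.element_region[:] = int(TissueClass.SOFT)
        a = 0.1 * np.sqrt(3.0) / 2.0  # εxx=a, εyy=−a → ε_eq = 2a/√3 = 0.1

        def u(p):
            return (a * p[0], -a * p[1])

        lc = LoadCase(supports=boundary_supports(mesh, u))
        nu = np.zeros(mesh.n_elements)
        e0 = np.full(mesh.n_elements, 1e-3)
        soft = np.ones(mesh.n_elements, dtype=bool)
        res = solve_with_soft_tissue_iteration(mesh, e0, nu, lc, soft, tol=1e-6)
        assert res.e_elements == pytest.approx(
            soft_tissue_modulus(0.1) * 1e-3, rel=1e-4
        )

    def test_stump_iteration_converges(self, model1_mesh):
        from hosim.fe_solver import element_poisson
        from hosim.materials import MaterialParams
        from hosim.remodeling import _initial_state

        mats = MaterialParams()
        st = _initial_state(model1_mesh, mats)
        nu = element_poisson(st.tissue, mats)
        lc = build_load_case(model1_mesh)
        soft = st.tissue == int(TissueClass.SOFT)
        res = solve_with_soft_tissue_iteration(model1_mesh, st.e_elements, nu, lc, soft)
        assert res.iterations <= 30


class TestLoadCase:
    def test_upright_resultants(self):
        """With a vertical femur the applied resultants equal the printed
        medial (0, −237) N and lateral (5, 158) N."""
        from hosim.geometry import StumpParams, generate_stump_mesh

        mesh = generate_stump_mesh(
            StumpParams(femoral_alignment=0.0, target_elements=800)
        )
        lc = build_load_case(mesh)
        med = lc.nodal_forces[0][1]
        lat = lc.nodal_forces[1][1]
        assert med == pytest.approx([0.0, -237.0], abs=1e-9)
        assert lat == pytest.approx([5.0, 158.0], abs=1e-9)

    def test_rotation_30deg(self):
        v = rotate(np.array([0.0, -237.0]), 30.0)
        assert v == pytest.approx([118.5, -205.248], abs=0.01)

    def test_rotation_identity(self):
        v = rotate(np.array([5.0, 158.0]), 0.0)
        assert v == pytest.approx([5.0, 158.0], abs=1e-12)

    def test_loads_follow_femoral_axis(self, model1_mesh):
        """Input loads are rotated onto the femoral long axis (10° here)."""
        lc = build_load_case(model1_mesh)
        med = lc.nodal_forces[0][1]
        expected = rotate(np.array([0.0, -237.0]), 10.0)
        assert med == pytest.approx(expected, abs=0.5)

    def test_missing_node_sets_error(self, patch):
        with pytest.raises(SolverError, match="node set"):
            build_load_case(patch)


def test_equivalent_strain_uniaxial():
    """Uniaxial strain state with lateral contraction: ε_eq = (2/3)(1+ν)ε."""
    nu = np.array([0.47])
    eps = 0.1
    strain = np.array([[eps, -nu[0] * eps, 0.0]])
    # plane-stress εzz equals εyy here, so e_eq has the closed form above
    got = equivalent_strain(strain, nu, "stress")
    ezz = -nu[0] / (1 - nu[0]) * (eps - nu[0] * eps)
    mean = (eps - nu[0] * eps + ezz) / 3
    dev = np.array([eps - mean, -nu[0] * eps - mean, ezz - mean])
    expected = np.sqrt(2 / 3 * (dev**2).sum())
    assert got[0] == pytest.approx(expected, rel=1e-12)
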