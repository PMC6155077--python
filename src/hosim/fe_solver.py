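"""Plane linear-elastic finite elements on 3-node triangles.

Constant-strain triangles (CST) with a single central integration
point, vectorized sparse assembly, direct factorization, consistent
edge-pressure loads, and a fixed-point secant iteration for the
strain-dependent soft-tissue modulus.

Units: coordinates mm, forces N, moduli/stresses MPa, pressures MPa.
Strain energy density in MPa is numerically J/cm³, so SED/ρ with ρ in
g/cm³ is J/g.  Out-of-plane thickness is 1 cm (a unit-thickness coronal
slab).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from hosim.geometry import StumpMesh, element_geometry
from hosim.materials import (
    TissueClass,
    MaterialParams,
    modulus_from_density,
    soft_tissue_modulus,
)

__all__ = [
    "THICKNESS_MM",
    "Support",
    "LoadCase",
    "FieldResult",
    "SolverError",
    "assemble_and_solve",
    "solve_with_soft_tissue_iteration",
    "build_load_case",
    "rotate",
    "equivalent_strain",
    "initial_element_moduli",
]

THICKNESS_MM = 10.0  # unit-thickness (1 cm) 2D slab

# baseline "upright" resultants (N): medial and lateral proximal cortical bands
UPRIGHT_MEDIAL_N = np.array([0.0, -237.0])
UPRIGHT_LATERAL_N = np.array([5.0, 158.0])


class SolverError(RuntimeError):
    pass


@dataclass
class Support:
    """Prescribed displacement on a node set; ``None`` leaves a DOF free."""

    nodes: np.ndarray
    ux: float | None = 0.0
    uy: float | None = 0.0


@dataclass
class LoadCase:
    """Nodal resultants, edge pressures and supports.

    ``nodal_forces``: (node set, total resultant N) — the resultant is
    spread evenly over the set's nodes.  ``edge_pressures``: (edge
    array, pressure MPa) with positive pressure acting inward
    (compressive on the boundary); suction is negative.
    """

    nodal_forces: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    edge_pressures: list[tuple[np.ndarray, float]] = field(default_factory=list)
    supports: list[Support] = field(default_factory=list)
    name: str = ""


@dataclass
class FieldResult:
    """Solution fields: nodal displacements (mm), per-element strain
    (εxx, εyy, γxy), stress (MPa), SED (MPa ≡ J/cm³), support reactions
    (N), and the converged soft-tissue moduli (MPa)."""

    displacements: np.ndarray
    strain: np.ndarray
    stress: np.ndarray
    sed: np.ndarray
    reactions: np.ndarray  # (n_constrained_dofs,)
    reaction_dofs: np.ndarray
    applied: np.ndarray  # assembled external force vector
    e_elements: np.ndarray  # per-element moduli used in the final solve (MPa)
    iterations: int = 1


def rotate(v: np.ndarray, degrees: float) -> np.ndarray:
    """Rotate a 2-vector anticlockwise."""
    th = np.deg2rad(degrees)
    c, s = np.cos(th), np.sin(th)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _elasticity_matrices(e: np.ndarray, nu: np.ndarray, plane: str) -> np.ndarray:
    """(m, 3, 3) constitutive matrices."""
    m = len(e)
    d = np.zeros((m, 3, 3))
    if plane == "stress":
        f = e / (1.0 - nu**2)
        d[:, 0, 0] = d[:, 1, 1] = f
        d[:, 0, 1] = d[:, 1, 0] = f * nu
        d[:, 2, 2] = f * (1.0 - nu) / 2.0
    elif plane == "strain":
        f = e / ((1.0 + nu) * (1.0 - 2.0 * nu))
        d[:, 0, 0] = d[:, 1, 1] = f * (1.0 - nu)
        d[:, 0, 1] = d[:, 1, 0] = f * nu
        d[:, 2, 2] = f * (1.0 - 2.0 * nu) / 2.0
    else:
        raise ValueError("plane must be 'stress' or 'strain'")
    return d


def _b_matrices(nodes: np.ndarray, triangles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """CST strain-displacement matrices (m, 3, 6) and areas (m,)."""
    p = nodes[triangles]
    x, y = p[..., 0], p[..., 1]
    b_i = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c_i = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    area2 = x[:, 0] * b_i[:, 0] + x[:, 1] * b_i[:, 1] + x[:, 2] * b_i[:, 2]
    m = len(triangles)
    b = np.zeros((m, 3, 6))
    b[:, 0, 0::2] = b_i
    b[:, 1, 1::2] = c_i
    b[:, 2, 0::2] = c_i
    b[:, 2, 1::2] = b_i
    b /= area2[:, None, None]
    return b, area2 / 2.0


def _assemble(mesh: StumpMesh, e: np.ndarray, nu: np.ndarray, plane: str):
    b, areas = _b_matrices(mesh.nodes, mesh.triangles)
    if np.any(areas <= 0):
        raise SolverError("mesh contains non-positive-area triangles")
    d = _elasticity_matrices(e, nu, plane)
    ke = np.einsum("mji,mjk,mkl,m->mil", b, d, b, areas * THICKNESS_MM)
    dofs = np.empty((len(mesh.triangles), 6), dtype=int)
    dofs[:, 0::2] = 2 * mesh.triangles
    dofs[:, 1::2] = 2 * mesh.triangles + 1
    rows = np.repeat(dofs, 6, axis=1).ravel()
    cols = np.tile(dofs, (1, 6)).ravel()
    n = 2 * mesh.n_nodes
    k = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsc()
    return k, b, areas


def _external_forces(mesh: StumpMesh, load_case: LoadCase) -> np.ndarray:
    f = np.zeros(2 * mesh.n_nodes)
    for nodes, total in load_case.nodal_forces:
        nodes = np.asarray(nodes, dtype=int)
        per = np.asarray(total, dtype=float) / len(nodes)
        f[2 * nodes] += per[0]
        f[2 * nodes + 1] += per[1]
    for edges, p_mpa in load_case.edge_pressures:
        a = mesh.nodes[edges[:, 0]]
        bpt = mesh.nodes[edges[:, 1]]
        t = bpt - a
        lengths = np.linalg.norm(t, axis=1)
        # domain lies left of a→b for CCW windings → outward normal (ty, −tx)
        n_out = np.column_stack([t[:, 1], -t[:, 0]]) / lengths[:, None]
        traction = -p_mpa * n_out  # positive pressure pushes inward
        fe = traction * (lengths * THICKNESS_MM / 2.0)[:, None]
        for col in (0, 1):
            np.add.at(f, 2 * edges[:, col], fe[:, 0])
            np.add.at(f, 2 * edges[:, col] + 1, fe[:, 1])
    return f


def _constraints(load_case: LoadCase, n_dofs: int) -> tuple[np.ndarray, np.ndarray]:
    fixed = {}
    for sup in load_case.supports:
        for node in np.asarray(sup.nodes, dtype=int):
            if sup.ux is not None:
                fixed[2 * node] = sup.ux
            if sup.uy is not None:
                fixed[2 * node + 1] = sup.uy
    if len(fixed) < 3:
        raise SolverError(
            f"only {len(fixed)} constrained DOFs; at least 3 needed to fix rigid-body modes"
        )
    idx = np.array(sorted(fixed), dtype=int)
    vals = np.array([fixed[i] for i in idx])
    return idx, vals


def assemble_and_solve(
    mesh: StumpMesh,
    e_elements: np.ndarray,
    nu_elements: np.ndarray,
    load_case: LoadCase,
    plane: str = "stress",
) -> FieldResult:
    """Assemble and solve the linear system; return displacement,
    strain, stress, SED and reaction fields.

    The equilibrium invariant (Σ reactions = −Σ applied loads) holds to
    solver precision by construction of the reactions from the
    assembled stiffness.
    """
    e_elements = np.asarray(e_elements, dtype=float)
    if np.any(e_elements <= 0):
        raise SolverError("non-positive element modulus")
    k, b, areas = _assemble(mesh, e_elements, nu_elements, plane)
    f = _external_forces(mesh, load_case)
    n = 2 * mesh.n_nodes
    c_idx, c_val = _constraints(load_case, n)
    free = np.setdiff1d(np.arange(n), c_idx)
    kff = k[free][:, free]
    rhs = f[free] - k[free][:, c_idx] @ c_val
    try:
        lu = splu(kff.tocsc())
        uf = lu.solve(rhs)
    except RuntimeError as exc:  # pragma: no cover - singular system
        raise SolverError(f"singular stiffness matrix: {exc}") from exc
    if not np.all(np.isfinite(uf)):
        raise SolverError("solver produced non-finite displacements")
    u = np.zeros(n)
    u[free] = uf
    u[c_idx] = c_val

    ue = u.reshape(-1, 2)[mesh.triangles].reshape(len(mesh.triangles), 6)
    strain = np.einsum("mij,mj->mi", b, ue)
    d = _elasticity_matrices(e_elements, nu_elements, plane)
    stress = np.einsum("mij,mj->mi", d, strain)
    sed = 0.5 * np.einsum("mi,mi->m", stress, strain)
    reactions = (k @ u - f)[c_idx]
    return FieldResult(
        displacements=u.reshape(-1, 2),
        strain=strain,
        stress=stress,
        sed=sed,
        reactions=reactions,
        reaction_dofs=c_idx,
        applied=f,
        e_elements=e_elements,
    )


def equivalent_strain(strain: np.ndarray, nu: np.ndarray, plane: str = "stress") -> np.ndarray:
    """Von-Mises-equivalent strain magnitude of the 2D strain state.

    The out-of-plane normal strain is recovered from the plane-stress
    (or plane-strain) condition before taking the deviatoric norm
    ε_eq = √(2/3 · e:e).
    """
    exx, eyy, gxy = strain[:, 0], strain[:, 1], strain[:, 2]
    if plane == "stress":
        ezz = -nu / (1.0 - nu) * (exx + eyy)
    else:
        ezz = np.zeros_like(exx)
    mean = (exx + eyy + ezz) / 3.0
    dxx, dyy, dzz = exx - mean, eyy - mean, ezz - mean
    exy = gxy / 2.0
    ee = dxx**2 + dyy**2 + dzz**2 + 2.0 * exy**2
    return np.sqrt(2.0 / 3.0 * ee)


def initial_element_moduli(
    mesh: StumpMesh,
    rho: np.ndarray,
    tissue: np.ndarray,
    mats: MaterialParams,
) -> np.ndarray:
    """Per-element moduli (MPa): bone/HO from density, fixed layers from
    the material table, soft tissue at the secant initial guess."""
    e = np.zeros(mesh.n_elements)
    for cls in (TissueClass.CORTICAL, TissueClass.TRABECULAR, TissueClass.HO):
        m = tissue == int(cls)
        if m.any():
            e[m] = modulus_from_density(cls, rho[m]) * 1e3  # GPa → MPa
    soft = tissue == int(TissueClass.SOFT)
    e[soft] = soft_tissue_modulus(mats.soft_strain_guess) * 1e-3  # kPa → MPa
    e[tissue == int(TissueClass.SKIN)] = mats.e_skin
    e[tissue == int(TissueClass.LINER)] = mats.e_liner
    e[tissue == int(TissueClass.SOCKET)] = mats.e_socket
    return e


def element_poisson(tissue: np.ndarray, mats: MaterialParams) -> np.ndarray:
    nu = np.empty(len(tissue))
    for cls, v in mats.poisson.items():
        nu[tissue == int(cls)] = v
    return nu


def solve_with_soft_tissue_iteration(
    mesh: StumpMesh,
    e_elements: np.ndarray,
    nu_elements: np.ndarray,
    load_case: LoadCase,
    soft_mask: np.ndarray,
    plane: str = "stress",
    tol: float = 1e-3,
    max_iter: int = 30,
) -> FieldResult:
    """Fixed-point secant iteration for strain-dependent soft tissue.

    Solves, recomputes each soft element's equivalent strain, updates
    its secant modulus from the passive-muscle curve, and repeats until
    the largest relative modulus change drops below ``tol``.  The
    incoming ``e_elements`` seed the iteration (warm starts across
    remodeling iterations converge in one or two solves).
    """
    e = np.asarray(e_elements, dtype=float).copy()
    f = _external_forces(mesh, load_case)
    prescribed_nonzero = any(
        (s.ux not in (None, 0.0)) or (s.uy not in (None, 0.0)) for s in load_case.supports
    )
    if not np.any(f) and not prescribed_nonzero:
        # unloaded: zero strain everywhere, soft moduli at the ε=0 floor
        e[soft_mask] = soft_tissue_modulus(0.0) * 1e-3
        res = assemble_and_solve(mesh, e, nu_elements, load_case, plane)
        res.iterations = 1
        return res
    last_residual = np.inf
    lam = 0.5  # Aitken dynamic relaxation factor, adapted per iteration
    r_prev: np.ndarray | None = None
    for it in range(1, max_iter + 1):
        res = assemble_and_solve(mesh, e, nu_elements, load_case, plane)
        if not soft_mask.any():
            res.iterations = it
            return res
        eps = equivalent_strain(res.strain[soft_mask], nu_elements[soft_mask], plane)
        e_new = soft_tissue_modulus(eps) * 1e-3  # kPa → MPa
        rel = np.max(np.abs(e_new - e[soft_mask]) / np.maximum(e[soft_mask], 1e-12))
        if rel < tol:
            res.iterations = it
            return res
        # Aitken-relaxed update in log-modulus space (the secant map
        # oscillates on the stiff passive-muscle curve)
        r = np.log(e_new) - np.log(e[soft_mask])
        if r_prev is not None:
            dr = r - r_prev
            denom = float(dr @ dr)
            if denom > 0.0:
                lam = float(np.clip(-lam * (r_prev @ dr) / denom, 0.05, 1.0))
        e[soft_mask] = np.exp(np.log(e[soft_mask]) + lam * r)
        r_prev = r
        last_residual = rel
    raise SolverError(
        f"soft-tissue secant iteration did not converge in {max_iter} iterations "
        f"(last relative modulus change {last_residual:.3g})"
    )


def build_load_case(
    mesh: StumpMesh,
    rotation_deg: float = 0.0,
    align_with_femur: bool = True,
    lateral_horizontal_sign: float = 1.0,
    edge_pressures: list[tuple[np.ndarray, float]] | None = None,
    name: str = "upright",
) -> LoadCase:
    """Baseline proximal-femur loading, optionally rotated.

    The medial resultant (0, −237) N and lateral resultant (5, 158) N
    are spread evenly over the proximal cortical medial/lateral node
    bands.  Loads are first rotated to align with the femoral long axis
    and then by ``rotation_deg`` (anticlockwise positive; +30° models
    abducted gait, −30° adducted).  The sign of the 5 N horizontal
    lateral component is configurable (its anatomical sign convention is
    ambiguous).  Supports fix the socket-base arc in x and y.
    """
    for key in ("proximal_cortical_medial", "proximal_cortical_lateral"):
        if key not in mesh.node_sets:
            raise SolverError(f"mesh is missing the '{key}' node set")
    align = 0.0
    if align_with_femur:
        ax = mesh.femoral_axis / np.linalg.norm(mesh.femoral_axis)
        align = np.rad2deg(np.arctan2(-ax[0], ax[1]))
    total_rot = rotation_deg + align
    medial = rotate(UPRIGHT_MEDIAL_N, total_rot)
    lateral = UPRIGHT_LATERAL_N * np.array([lateral_horizontal_sign, 1.0])
    lateral = rotate(lateral, total_rot)
    if "socket_base" not in mesh.node_sets:
        raise SolverError("mesh is missing the 'socket_base' node set")
    return LoadCase(
        nodal_forces=[
            (mesh.node_sets["proximal_cortical_medial"], medial),
            (mesh.node_sets["proximal_cortical_lateral"], lateral),
        ],
        edge_pressures=list(edge_pressures or []),
        supports=[Support(mesh.node_sets["socket_base"], 0.0, 0.0)],
        name=name,
    )
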