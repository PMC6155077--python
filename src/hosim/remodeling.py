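"""Adaptive density remodeling with a spatially weighted stimulus.

Each remodeling-eligible element (cortical, trabecular, HO, soft) both
senses and responds to a strain-energy stimulus.  The sensed error of
element *i* is SED_i/ρ_i − K_i (J/g), optionally gated by a lazy zone
of ±s·K_i; the stimulus at a target element *x* is the
exponentially-weighted sum Σ_i e^(−d_i(x)/D) · err_i over all eligible
sensors (self included at distance zero).  The density update is

    ρ(x)_{t+Δt} = ρ(x)_t + τ · φ(x)_t · β(x)_t

where β = P^(1/(1.5·ρ_MSC)) couples the substrate-stiffness
ossification probability P to the mesenchymal-cell proximity field
ρ_MSC, localizing new bone near the wound.  Soft tissue crossing the
1.2 g/cm³ density threshold transitions irreversibly to HO, after which
its stiffness follows the bone density–modulus law.

Skin, liner and socket elements are neither sensors nor targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from hosim.geometry import StumpMesh, element_geometry, CM
from hosim.materials import (
    TissueClass,
    MaterialParams,
    REMODELING_CLASSES,
    modulus_from_density,
    ossification_probability,
    apply_density_clamp,
    transition_tissue_array,
)
from hosim.fe_solver import (
    element_poisson,
    initial_element_moduli,
    solve_with_soft_tissue_iteration,
)

__all__ = [
    "RemodelParams",
    "CellFieldMode",
    "CellField",
    "RemodelState",
    "mesenchymal_field",
    "beta_field",
    "stimulus_field",
    "stimulus_field_bruteforce",
    "sensor_weights",
    "update_density",
    "run_simulation",
]


@dataclass
class RemodelParams:
    """Remodeling constants.

    ``k`` is the steady-state reference stimulus per tissue (J/g) —
    lower for HO and soft tissue than for skeletal bone, reflecting the
    reduced load transmission away from the skeleton.  ``d_mm`` is the
    sensor influence distance D (0.35 cm).  ``lazy_span`` is the dead
    band around K as a fraction of K (10% for femoral bone, none for HO
    and soft tissue).  Convergence: mean |Δρ| over eligible elements
    below ``convergence_threshold`` g/cm³ per iteration, hard stop at
    ``max_iterations``.
    """

    k: dict[TissueClass, float] = field(
        default_factory=lambda: {
            TissueClass.CORTICAL: 0.0429,
            TissueClass.TRABECULAR: 0.0125,
            TissueClass.HO: 0.0029,
            TissueClass.SOFT: 0.0029,
        }
    )
    d_mm: float = 3.5
    tau: float = 1.0
    lazy_span: dict[TissueClass, float] = field(
        default_factory=lambda: {
            TissueClass.CORTICAL: 0.10,
            TissueClass.TRABECULAR: 0.10,
            TissueClass.HO: 0.0,
            TissueClass.SOFT: 0.0,
        }
    )
    convergence_threshold: float = 1e-4  # g/cm³ per iteration
    max_iterations: int = 1250
    #: sensor cutoff radius as a multiple of D (weight e^−20 ≈ 2e−9)
    cutoff_factor: float = 20.0
    #: Eq-3 exponent convention: "reciprocal" → P^(1/(1.5·ρ_MSC)),
    #: "product" → P^(ρ_MSC/1.5)
    beta_exponent: str = "reciprocal"
    transition_threshold: float = 1.2

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.k.values()) or self.d_mm <= 0:
            raise ValueError("K values and D must be positive")
        if any(not 0 <= s < 1 for s in self.lazy_span.values()):
            raise ValueError("lazy spans must lie in [0, 1)")
        if self.convergence_threshold <= 0:
            raise ValueError("convergence threshold must be positive")


class CellFieldMode(str, Enum):
    DISTAL_LINEAR = "distal_linear"
    RADIAL_FROM_POINT = "radial_from_point"


@dataclass
class CellField:
    """Normalized mesenchymal-stem-cell density per element ∈ [0.01, 1],
    peaking at the wound and decaying linearly with distance."""

    rho_msc: np.ndarray
    wound_point: np.ndarray
    mode: CellFieldMode


@dataclass
class RemodelState:
    """Per-element simulation state plus run history."""

    rho: np.ndarray  # g/cm³
    tissue: np.ndarray  # TissueClass int codes
    e_elements: np.ndarray  # MPa
    beta: np.ndarray
    phi: np.ndarray
    sed: np.ndarray
    iteration: int = 0
    mean_drho_history: list[float] = field(default_factory=list)
    ho_area_history: list[float] = field(default_factory=list)
    converged_at: int | None = None
    snapshots: list[tuple[int, np.ndarray, np.ndarray]] = field(default_factory=list)

    def eligible_mask(self) -> np.ndarray:
        return np.isin(self.tissue, [int(c) for c in REMODELING_CLASSES])


def mesenchymal_field(
    mesh: StumpMesh,
    wound: np.ndarray | tuple[float, float] | None = None,
    mode: CellFieldMode = CellFieldMode.DISTAL_LINEAR,
) -> CellField:
    """Linear wound-proximity field: 1 at the wound, 0.01 at the
    farthest element centroid.

    DISTAL_LINEAR anchors the wound at the distal-most mesh point;
    RADIAL_FROM_POINT decays radially from an explicit wound point,
    which must lie inside the mesh bounding box.
    """
    cent, _ = element_geometry(mesh)
    if mode is CellFieldMode.DISTAL_LINEAR:
        # distal-most point of the tissue surface (not of any socket ring)
        if "outer_skin" in mesh.boundary_edges and len(mesh.boundary_edges["outer_skin"]):
            skin_nodes = np.unique(mesh.boundary_edges["outer_skin"])
            wound_pt = mesh.nodes[skin_nodes[np.argmin(mesh.nodes[skin_nodes, 1])]]
        else:
            wound_pt = mesh.nodes[np.argmin(mesh.nodes[:, 1])]
    else:
        if wound is None:
            raise ValueError("RADIAL_FROM_POINT requires a wound point")
        wound_pt = np.asarray(wound, dtype=float)
        lo = mesh.nodes.min(axis=0) - 1e-9
        hi = mesh.nodes.max(axis=0) + 1e-9
        if np.any(wound_pt < lo) or np.any(wound_pt > hi):
            raise ValueError(f"wound point {wound_pt} outside the mesh bounding box")
    d = np.linalg.norm(cent - wound_pt, axis=1)
    dmax = d.max()
    rho_msc = 1.0 + (0.01 - 1.0) * d / dmax
    return CellField(np.clip(rho_msc, 0.01, 1.0), wound_pt, mode)


def beta_field(p: np.ndarray, rho_msc: np.ndarray, exponent: str = "reciprocal") -> np.ndarray:
    """β = P^(1/(1.5·ρ_MSC)) element-wise, in (0, 1].

    The reciprocal exponent makes β collapse toward zero far from the
    wound (large exponent on P < 1), localizing ossification; the
    alternative "product" reading P^(ρ_MSC/1.5) is provided for
    sensitivity studies.
    """
    p = np.asarray(p, dtype=float)
    rho_msc = np.asarray(rho_msc, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("P must lie in (0, 1]")
    if np.any(rho_msc < 0.01 - 1e-12) or np.any(rho_msc > 1 + 1e-12):
        raise ValueError("rho_MSC must lie in [0.01, 1]")
    if exponent == "reciprocal":
        expo = 1.0 / (1.5 * rho_msc)
    elif exponent == "product":
        expo = rho_msc / 1.5
    else:
        raise ValueError("beta_exponent must be 'reciprocal' or 'product'")
    return np.power(p, expo)


def _gated_errors(
    sed: np.ndarray, rho: np.ndarray, tissue: np.ndarray, params: RemodelParams
) -> np.ndarray:
    """Sensor errors SED/ρ − K with per-sensor lazy-zone gating."""
    if np.any(rho <= 0):
        raise ValueError("zero or negative density in stimulus computation")
    err = np.empty_like(sed)
    for cls in REMODELING_CLASSES:
        m = tissue == int(cls)
        if not m.any():
            continue
        k = params.k[cls]
        e = sed[m] / rho[m] - k
        span = params.lazy_span[cls]
        if span > 0:
            e = np.where(np.abs(e) <= span * k, 0.0, e)
        err[m] = e
    return err


def sensor_weights(
    centroids: np.ndarray, params: RemodelParams, cutoff: bool = True
) -> sp.csr_matrix:
    """Sparse pairwise weight matrix w_ij = exp(−d_ij/D), zero beyond
    the cutoff radius.  Symmetric; diagonal is 1 (self-sensing)."""
    if cutoff:
        r = params.cutoff_factor * params.d_mm
        tree = cKDTree(centroids)
        coo = tree.sparse_distance_matrix(tree, r, output_type="coo_matrix")
        w = sp.coo_matrix(
            (np.exp(-coo.data / params.d_mm), (coo.row, coo.col)), shape=coo.shape
        ).tocsr()
        # sparse_distance_matrix drops explicit zeros; restore the diagonal
        w = w.tolil()
        w.setdiag(1.0)
        return w.tocsr()
    d = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=2)
    return sp.csr_matrix(np.exp(-d / params.d_mm))


def stimulus_field(
    centroids: np.ndarray,
    sed: np.ndarray,
    rho: np.ndarray,
    tissue: np.ndarray,
    params: RemodelParams,
    weights: sp.csr_matrix | None = None,
) -> np.ndarray:
    """Stimulus φ per eligible element (arrays restricted to the
    eligible set).  ``weights`` may be precomputed once per mesh."""
    err = _gated_errors(sed, rho, tissue, params)
    if weights is None:
        weights = sensor_weights(centroids, params)
    return np.asarray(weights @ err)


def stimulus_field_bruteforce(
    centroids: np.ndarray,
    sed: np.ndarray,
    rho: np.ndarray,
    tissue: np.ndarray,
    params: RemodelParams,
) -> np.ndarray:
    """All-pairs reference implementation (no cutoff): the oracle the
    accelerated path is verified against."""
    err = _gated_errors(sed, rho, tissue, params)
    diff = centroids[:, None, :] - centroids[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    return (np.exp(-d / params.d_mm) * err[None, :]).sum(axis=1)


def update_density(
    rho: np.ndarray,
    tissue: np.ndarray,
    phi: np.ndarray,
    beta: np.ndarray,
    params: RemodelParams,
    eligible: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Apply the density update to eligible elements, clamp each class
    to its density range, transition SOFT→HO at the threshold, and
    return (ρ', tissue', mean |Δρ| over eligible elements)."""
    rho_new = rho.copy()
    rho_new[eligible] = rho[eligible] + params.tau * phi * beta
    # transition first so a soft element overshooting the threshold keeps
    # its density inside the (wider) HO range
    tissue_new = transition_tissue_array(tissue, rho_new, params.transition_threshold)
    for cls in REMODELING_CLASSES:
        m = tissue_new == int(cls)
        if m.any():
            rho_new[m] = apply_density_clamp(cls, rho_new[m])
    mean_drho = float(np.abs(rho_new[eligible] - rho[eligible]).mean())
    return rho_new, tissue_new, mean_drho


def _initial_state(mesh: StumpMesh, mats: MaterialParams) -> RemodelState:
    n = mesh.n_elements
    tissue = mesh.element_region.copy()
    rho = np.zeros(n)
    for cls, r0 in mats.rho_initial.items():
        rho[tissue == int(cls)] = r0
    rho[tissue == int(TissueClass.SKIN)] = mats.rho_initial[TissueClass.SOFT]
    e = initial_element_moduli(mesh, rho, tissue, mats)
    return RemodelState(
        rho=rho,
        tissue=tissue,
        e_elements=e,
        beta=np.ones(n),
        phi=np.zeros(n),
        sed=np.zeros(n),
    )


def run_simulation(
    mesh: StumpMesh,
    schedule,
    params: RemodelParams | None = None,
    mats: MaterialParams | None = None,
    cell_field: CellField | None = None,
    snapshot_stride: int = 0,
    plane: str = "stress",
    progress: bool = False,
    log_rows: list | None = None,
) -> RemodelState:
    """Run the remodeling loop until convergence or the iteration cap.

    Per iteration: scheduled load case → FE solve with the soft-tissue
    secant iteration (warm-started from the previous iteration) →
    ossification probability from current element stiffness → β → φ →
    density update with clamping and SOFT→HO transitions → bone/HO
    stiffness refresh from density.  Fully deterministic for fixed
    inputs.
    """
    from hosim.scenarios import Schedule  # local import to avoid a cycle

    if params is None:
        params = RemodelParams()
    if mats is None:
        mats = MaterialParams()
    if isinstance(schedule, Schedule) and schedule.material_overrides:
        mats = schedule.apply_overrides(mats)
    state = _initial_state(mesh, mats)
    if cell_field is None:
        if isinstance(schedule, Schedule) and schedule.cell_field is not None:
            cell_field = schedule.cell_field
        else:
            cell_field = mesenchymal_field(mesh)
    nu = element_poisson(state.tissue, mats)
    cent, areas = element_geometry(mesh)
    eligible = state.eligible_mask()  # fixed: SOFT→HO stays eligible
    weights = sensor_weights(cent[eligible], params)
    rho_msc_el = cell_field.rho_msc[eligible]
    bone_codes = [int(TissueClass.CORTICAL), int(TissueClass.TRABECULAR), int(TissueClass.HO)]

    max_it = params.max_iterations
    # multi-phase schedules (pressure dressing, tourniquet) have fixed
    # prescribed phases; the convergence stop applies in the final phase
    conv_from = 1
    if isinstance(schedule, Schedule):
        max_it = min(max_it, schedule.end_iteration())
        conv_from = schedule.phases[-1][1]
    for it in range(1, max_it + 1):
        state.iteration = it
        load_case = (
            schedule.load_case_for(it) if isinstance(schedule, Schedule) else schedule
        )
        soft_mask = state.tissue == int(TissueClass.SOFT)
        result = solve_with_soft_tissue_iteration(
            mesh, state.e_elements, nu, load_case, soft_mask, plane=plane
        )
        state.e_elements = result.e_elements
        state.sed = result.sed

        p = ossification_probability(
            state.e_elements[eligible], mats.anchors, tissue=state.tissue[eligible]
        )
        beta = beta_field(p, rho_msc_el, params.beta_exponent)
        phi = stimulus_field(
            cent[eligible],
            state.sed[eligible],
            state.rho[eligible],
            state.tissue[eligible],
            params,
            weights,
        )
        state.beta = np.zeros(mesh.n_elements)
        state.beta[eligible] = beta
        state.phi = np.zeros(mesh.n_elements)
        state.phi[eligible] = phi

        state.rho, tissue_new, mean_drho = update_density(
            state.rho, state.tissue, phi, beta, params, eligible
        )
        transitioned = tissue_new != state.tissue
        state.tissue = tissue_new
        if transitioned.any():
            nu = element_poisson(state.tissue, mats)
        for code in bone_codes:
            m = state.tissue == code
            if m.any():
                state.e_elements[m] = (
                    modulus_from_density(TissueClass(code), state.rho[m]) * 1e3
                )

        ho_mask = state.tissue == int(TissueClass.HO)
        ho_area = float(areas[ho_mask].sum() / CM**2)
        state.mean_drho_history.append(mean_drho)
        state.ho_area_history.append(ho_area)
        if log_rows is not None:
            log_rows.append((it, mean_drho, ho_area, result.iterations))
        if snapshot_stride and (it % snapshot_stride == 0):
            state.snapshots.append((it, state.rho.copy(), state.tissue.copy()))
        if progress and (it % 50 == 0 or it == 1):
            print(
                f"iter {it:5d}  mean|dρ|={mean_drho:.3e}  HO area={ho_area:.2f} cm²",
                flush=True,
            )
        if (
            state.converged_at is None
            and it >= conv_from
            and mean_drho < params.convergence_threshold
        ):
            state.converged_at = it
            break
    return state
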