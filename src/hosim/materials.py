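"""Constitutive laws and tissue transitions.

Density–modulus polynomials for cortical / trabecular / heterotopic
bone, the strain-dependent secant modulus of passive muscle, the
substrate-stiffness ossification probability *P*, per-class density
ranges, and the one-way soft→HO tissue transition.

Unit conventions
----------------
* density ρ : g/cm³
* modulus from :func:`modulus_from_density` : GPa (as the fitted
  polynomials are printed); the FE layer works in MPa
* soft-tissue modulus : kPa
* ossification-probability anchors : MPa

With lengths in mm and stresses in MPa, a strain energy density in MPa
is numerically J/cm³, so SED/ρ is J/g with no conversion factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "TissueClass",
    "MaterialParams",
    "OssProbAnchors",
    "modulus_from_density",
    "soft_tissue_modulus",
    "ossification_probability",
    "apply_density_clamp",
    "transition_tissue",
    "DENSITY_RANGES",
    "REMODELING_CLASSES",
]


class TissueClass(IntEnum):
    """Tissue classes.  SKIN, LINER and SOCKET never remodel; HO arises
    only from SOFT and never reverts."""

    CORTICAL = 0
    TRABECULAR = 1
    HO = 2
    SOFT = 3
    SKIN = 4
    LINER = 5
    SOCKET = 6


#: classes whose elements both sense and respond to the remodeling stimulus
REMODELING_CLASSES = (
    TissueClass.CORTICAL,
    TissueClass.TRABECULAR,
    TissueClass.HO,
    TissueClass.SOFT,
)

#: bone-like classes: P = 1 regardless of modulus
BONE_CLASSES = (TissueClass.CORTICAL, TissueClass.TRABECULAR, TissueClass.HO)

# density ranges (g/cm³); lower bounds are open in the source convention,
# implemented as closed with a small tolerance
_RANGE_TOL = 1e-9
DENSITY_RANGES: dict[TissueClass, tuple[float, float]] = {
    TissueClass.CORTICAL: (1.2, 2.0),
    TissueClass.TRABECULAR: (0.1, 1.2),
    TissueClass.HO: (0.1, 2.2),
    TissueClass.SOFT: (0.1, 1.2),  # soft density drifts below the HO threshold
}

# E(ρ) in GPa, coefficients low→high order
_POLY_CORTICAL = (-2.642, 5.622, 0.763, 0.937)
_POLY_TRABECULAR = (-0.07, 1.575, 0.762, 1.241)  # identical for HO
# E_soft(ε) in kPa
_POLY_SOFT = (0.04, 124.41, -479.66, 2725.02)

#: fitted strain range of the soft-tissue curve; ε clamped here
SOFT_STRAIN_MAX = 0.6
#: floor for the bone polynomials (GPa); the cubics go negative below
#: their fitted density range
_E_BONE_FLOOR_GPA = 1e-3


@dataclass(frozen=True)
class OssProbAnchors:
    """(modulus MPa, probability) anchors of the ossification-probability
    curve, interpolated piecewise-linearly in log10(E).

    Defaults: cartilage-like 10 MPa → 0.10, soft callus 1 GPa → 0.60,
    intermediate callus 3 GPa → 0.87, stiff callus (saturation,
    ``e_stiff``) → 1.00.  Below the first anchor the curve is
    extrapolated on the same log-linear slope and clamped at ``p_floor``.
    """

    anchors: tuple[tuple[float, float], ...] = (
        (10.0, 0.10),
        (1000.0, 0.60),
        (3000.0, 0.87),
    )
    e_stiff: float = 6000.0
    p_floor: float = 0.01

    def __post_init__(self) -> None:
        pts = list(self.anchors) + [(self.e_stiff, 1.0)]
        es = [p[0] for p in pts]
        ps = [p[1] for p in pts]
        if any(e2 <= e1 for e1, e2 in zip(es, es[1:])) or any(
            p2 <= p1 for p1, p2 in zip(ps, ps[1:])
        ):
            raise ValueError("anchors must be strictly increasing in modulus and probability")
        if not all(0.0 < p <= 1.0 for p in ps):
            raise ValueError("anchor probabilities must lie in (0, 1]")


@dataclass
class MaterialParams:
    """Material parameter set: initial densities, fixed moduli of the
    non-remodeling layers, Poisson ratios, the soft→HO transition
    threshold, and the ossification-probability anchors.

    Moduli here are MPa (FE convention).  ``e_skin`` is 8 MPa
    (8000 kPa); the reduced-skin scenario overrides it to 0.06 MPa
    (60 kPa).
    """

    rho_initial: dict[TissueClass, float] = field(
        default_factory=lambda: {
            TissueClass.CORTICAL: 1.7,
            TissueClass.TRABECULAR: 0.8,
            TissueClass.SOFT: 0.95,
        }
    )
    e_skin: float = 8.0  # MPa = 8000 kPa
    e_socket: float = 15000.0  # MPa
    e_liner: float = 1.0  # MPa
    poisson: dict[TissueClass, float] = field(
        default_factory=lambda: {
            TissueClass.CORTICAL: 0.3,
            TissueClass.TRABECULAR: 0.3,
            TissueClass.HO: 0.3,
            TissueClass.SOFT: 0.47,
            TissueClass.SKIN: 0.475,
            TissueClass.LINER: 0.49,
            TissueClass.SOCKET: 0.3,
        }
    )
    transition_threshold: float = 1.2  # g/cm³, SOFT→HO
    anchors: OssProbAnchors = field(default_factory=OssProbAnchors)
    #: initial guess strain for the soft-tissue secant iteration
    soft_strain_guess: float = 0.05


def _polyval(coeffs: tuple[float, ...], x):
    out = np.zeros_like(np.asarray(x, dtype=float))
    for c in reversed(coeffs):
        out = out * x + c
    return out


def modulus_from_density(tissue: TissueClass, rho) -> np.ndarray | float:
    """Young's modulus (GPa) from apparent density (g/cm³).

    Cortical and trabecular bone use separately fitted cubics; HO uses
    the trabecular fit over its wider density range.  Values are floored
    at a small positive modulus.  ρ outside the class range is an error
    (clamping belongs to the remodeling step, not here).
    """
    rho_arr = np.asarray(rho, dtype=float)
    if tissue not in DENSITY_RANGES:
        raise ValueError(f"{tissue.name} has no density–modulus law")
    lo, hi = DENSITY_RANGES[tissue]
    if np.any(rho_arr < lo - _RANGE_TOL) or np.any(rho_arr > hi + _RANGE_TOL):
        raise ValueError(
            f"density out of {tissue.name} range ({lo}, {hi}]: "
            f"min={rho_arr.min():g} max={rho_arr.max():g}"
        )
    coeffs = _POLY_CORTICAL if tissue is TissueClass.CORTICAL else _POLY_TRABECULAR
    e = np.maximum(_polyval(coeffs, rho_arr), _E_BONE_FLOOR_GPA)
    return float(e) if np.isscalar(rho) else e


def soft_tissue_modulus(strain) -> np.ndarray | float:
    """Secant modulus (kPa) of passive soft tissue at equivalent strain ε.

    Cubic fit to passive longitudinal muscle tension tests; ε is clamped
    to the fitted maximum of 0.6 and the result floored at the ε = 0
    value (0.04 kPa).
    """
    eps = np.clip(np.asarray(strain, dtype=float), 0.0, SOFT_STRAIN_MAX)
    e = np.maximum(_polyval(_POLY_SOFT, eps), _POLY_SOFT[0])
    return float(e) if np.isscalar(strain) else e


def ossification_probability(
    e_mpa,
    anchors: OssProbAnchors | None = None,
    tissue: TissueClass | np.ndarray | None = None,
) -> np.ndarray | float:
    """Ossification probability P ∈ (0, 1] from current element modulus.

    Piecewise-linear in log10(E MPa) through the anchors; exactly 1 at
    and above the stiff-callus saturation modulus; extrapolated and
    clamped to ``p_floor`` below the first anchor.  Elements already
    classed as bone (cortical / trabecular / HO) get P = 1 regardless of
    modulus.
    """
    if anchors is None:
        anchors = OssProbAnchors()
    e_arr = np.asarray(e_mpa, dtype=float)
    if np.any(e_arr <= 0.0):
        raise ValueError("modulus must be positive")
    pts = list(anchors.anchors) + [(anchors.e_stiff, 1.0)]
    log_e = np.log10([p[0] for p in pts])
    probs = np.array([p[1] for p in pts])
    # linear extrapolation below the first anchor, then clamp
    slope0 = (probs[1] - probs[0]) / (log_e[1] - log_e[0])
    x = np.log10(e_arr)
    p = np.interp(x, log_e, probs)
    below = x < log_e[0]
    if np.any(below):
        p = np.where(below, probs[0] + slope0 * (x - log_e[0]), p)
    p = np.clip(p, anchors.p_floor, 1.0)
    if tissue is not None:
        if isinstance(tissue, TissueClass):
            if tissue in BONE_CLASSES:
                p = np.ones_like(p)
        else:
            bone = np.isin(np.asarray(tissue), [int(c) for c in BONE_CLASSES])
            p = np.where(bone, 1.0, p)
    return float(p) if np.isscalar(e_mpa) else p


def apply_density_clamp(tissue: TissueClass, rho) -> np.ndarray | float:
    """Clamp ρ into the class density range (idempotent).

    Lower bounds are open intervals in the source convention; the clamp
    lands a hair above the bound.
    """
    lo, hi = DENSITY_RANGES[tissue]
    out = np.clip(np.asarray(rho, dtype=float), lo + _RANGE_TOL, hi)
    return float(out) if np.isscalar(rho) else out


def transition_tissue(tissue: TissueClass, rho: float, threshold: float = 1.2) -> TissueClass:
    """One-way SOFT→HO transition at the density threshold.

    All other classes pass through unchanged (skin, liner and socket
    never remodel; HO never reverts to soft, though it may resorb toward
    its range floor).
    """
    if tissue is TissueClass.SOFT and rho >= threshold:
        return TissueClass.HO
    return tissue


def transition_tissue_array(tissue: np.ndarray, rho: np.ndarray, threshold: float = 1.2) -> np.ndarray:
    """Vectorized :func:`transition_tissue`."""
    out = tissue.copy()
    out[(tissue == int(TissueClass.SOFT)) & (rho >= threshold)] = int(TissueClass.HO)
    return out
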