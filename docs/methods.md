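# Methods

## Scope and intent

`hosim` models mechanically mediated heterotopic ossification (HO) in a 2D
coronal slice of a trans-femoral residual limb. The package couples an
adaptive bone-remodeling rule (strain-energy-density stimulus with a spatial
osteocyte-sensor kernel) to two biological gates — substrate-stiffness
ossification probability and a wound-proximity mesenchymal-cell field — so
that soft tissue can ossify where mechanical stimulus and biology coincide.
It is a research sandbox for loading interventions, not a patient-specific
predictive tool.

## Geometry

No patient geometry ships with the package; a parametric generator builds the
stump from clinical-scale dimensions (all cm): femur width at mid-shaft,
proximal limb width, limb length, soft-tissue area, femoral alignment from
vertical, and distal soft-tissue depth. Defaults follow a published
trans-femoral model: femur 2.7 cm, proximal width 13.8 cm, length 20.5 cm,
soft-tissue area 205 cm², alignment 10°, 5 cm of tissue distal to the femur
tip. The outline is the convex envelope of the proximal cut and a distal cap
circle whose radius is solved (Brent) to hit the soft-tissue area target, with
a 2 % barrel bulge on the tapered sides. The femur is a round-tipped shaft
about a tilted axis; the cortical shell (0.45 cm default) encloses a
trabecular core.

Meshing samples the three nested interfaces (skin surface, cortical,
trabecular) at the element size, fills the interior with a hexagonal point
lattice kept clear of the interfaces, Delaunay-triangulates, and classifies
elements by centroid containment. The outermost soft-element layer is
re-tagged SKIN (one element deep, ~2–3 mm at the default 3 mm element size).
Liner (0.6 cm) and socket (1.2 cm) are structured bands sharing nodes with
the skin surface — tied interfaces; frictional sliding is deliberately not
modeled. The socket is fixed over a 3.5 cm arc at the distal pole. The
generator's seed jitters only the boundary sampling phase; a fixed seed gives
a bit-identical mesh.

Conventions: x is medial (left-leg convention, configurable via the stored
medial–lateral axis), y is proximal; coordinates are mm internally. Positive
femoral alignment tilts the distal tip medially.

## Materials

| quantity | value |
|---|---|
| cortical density range / initial | (1.2, 2.0] g/cm³, 1.7 |
| trabecular range / initial | (0.1, 1.2], 0.8 |
| HO range | (0.1, 2.2] |
| soft initial density | 0.95 |
| E(ρ) cortical (GPa) | −2.642 + 5.622ρ + 0.763ρ² + 0.937ρ³ |
| E(ρ) trabecular = HO (GPa) | −0.07 + 1.575ρ + 0.762ρ² + 1.241ρ³ |
| E_soft(ε) (kPa) | 0.04 + 124.41ε − 479.66ε² + 2725.02ε³ |
| E skin / liner / socket | 8000 kPa / 1 MPa / 15 GPa |
| ν bone/soft/skin/liner/socket | 0.3 / 0.47 / 0.475 / 0.49 / 0.3 |

Numerical guards: the bone cubics go negative below their fitted range and
are floored at 1 MPa; the soft cubic is evaluated on ε ∈ [0, 0.6] (clamped
beyond the fitted strain) and floored at its ε = 0 value. Open-interval
density bounds are implemented as closed with a 1e-9 tolerance. The
trabecular and HO polynomials are identical, so the SOFT→HO transition has no
stiffness jump at 1.2 g/cm³.

The soft-tissue law is a *secant* modulus driven by the von-Mises-equivalent
strain of the 2D tensor (out-of-plane strain recovered from the plane-stress
condition). The tissue was characterized in longitudinal passive tension;
treating the equivalent strain as that scalar is an isotropy assumption.

**Ossification probability.** Published anchors only: (10 MPa, ~10 %),
(1 GPa, 60 %), (3 GPa, 87 %), stiff callus → 100 %. We interpolate
piecewise-linearly in log10(E) through (10 MPa, 0.10), (1 GPa, 0.60),
(3 GPa, 0.87), (E_stiff, 1.0) with E_stiff = 6 GPa (configurable), clamp to
1 above, and extrapolate on the first segment's slope clamped at a floor of
0.01 below. The floor keeps β strictly positive so the update never divides
attention by exactly zero; with the ρ_MSC floor of 0.01 the product is
numerically negligible far from the wound, which is the intended
localization. Bone-classed elements always return P = 1.

## Finite elements

Plane-stress (unit 1 cm thickness) constant-strain triangles with one central
integration point, sparse assembly, direct LU. Plane stress was chosen
because the coronal slab has free out-of-plane surfaces; a `plane="strain"`
switch exists. SED = ½ σ:ε at the integration point; in MPa it is numerically
J/cm³, so SED/ρ with ρ in g/cm³ is J/g with no conversion factor — the reason
the internal units are mm / N / MPa / g·cm⁻³.

Loads: the upright case applies the published proximal resultants — medial
(0, −237) N, lateral (5, 158) N — spread evenly over 1-cm proximal cortical
node bands and rotated onto the femoral long axis; gait variants rotate them
a further ±30° (anticlockwise = abduction; the sign and the 5 N lateral
horizontal sign are configurable, as the source conventions are not stated).
Pressures are consistent edge tractions on the skin boundary: negative
(suction) for the dressing, positive (inward) for the tourniquet.

The strain-dependent soft modulus makes each solve a fixed-point problem:
solve → equivalent strain → secant modulus → repeat. The bare iteration
oscillates on this strongly nonlinear curve, so the update is Aitken-relaxed
in log-modulus space (initial factor 0.5, adapted each step, clipped to
[0.05, 1]); convergence is max relative modulus change < 1e-3, typically
~14 solves cold and 1–3 warm-started from the previous remodeling iteration.
An exactly unloaded case short-circuits to the zero-strain floor.

## Remodeling loop

Parameters (defaults): K = 0.0429 (cortical), 0.0125 (trabecular), 0.0029
(HO and soft) J/g; D = 0.35 cm; τ = 1; lazy zone ±10 % of K for femoral bone,
none for HO/soft; SOFT→HO threshold 1.2 g/cm³; stop when mean |Δρ| over
eligible elements < 1e-4 g/cm³/iteration, hard cap 1250 iterations
(≈ 5 months; 1 iteration ≈ 3 h).

Every eligible element is both sensor and target; skin, liner and socket are
neither. Sensor errors are gated by the sensor's own lazy zone. The weight
matrix exp(−d/D) over eligible-element centroids is precomputed once per run
(eligibility never changes — SOFT→HO stays eligible); the production path
drops pairs beyond 20·D (weight ≈ 2e-9) via a KD-tree and is verified in the
tests against a dense all-pairs oracle to 1e-6.

Update order per iteration: FE solve → P from current element stiffness
(secant E for soft, density-law E for bone/HO) → β → φ → ρ += τφβ →
transition SOFT→HO at the threshold → clamp each class to its density range →
refresh bone/HO stiffness from density. Transition precedes clamping so an
overshooting soft element keeps its density inside the wider HO range. The
convergence metric uses post-clamp changes, so elements pinned at a range
bound contribute zero. For multi-phase schedules (dressing, tourniquet) the
prescribed early phases always run to completion; the stopping criterion is
evaluated only in the final phase.

β's exponent is read as P^(1/(1.5·ρ_MSC)) — the reading under which β
collapses far from the wound, matching the described localization of HO near
the injury; the alternative P^(ρ_MSC/1.5) is available as
`beta_exponent="product"` for sensitivity work.

## Behavior under the published constants

With the published loads, femoral SED/ρ (~1e-4 J/g) sits two orders below
K_cortical, so the femur resorbs to its density-range floors over the first
~20 iterations of any run; this is the faithful consequence of the printed
constants (the loads were derived in a different proximal-femur model whose
stimulus balance is not reproduced here) and does not affect HO formation,
which is driven by soft-tissue SED near the distal femur where strains are
large. On the baseline stump, soft tissue under the femur tip ossifies from
roughly iteration 130, grows into an attached, medially offset, elongated
spike (Type 1) of ~3 cm², and the run meets the stopping criterion around
iteration 270–320 depending on mesh seed.

The scenario suite reproduces, at desk scale: upright → Type 1; reduced skin
stiffness → markedly higher skin-contact fraction of the dominant patch
(crawling tendency); tourniquet → no soft-tissue bone after its single
iteration, with the femoral remodeling signal locally elevated (less
resorptive) near the cuff. It does **not** reproduce the abducted → detached
shell or adducted → lateral spike flips: those require the femur to displace
by centimetres within the stump (geometrically nonlinear kinematics with
frictional socket contact on patient-traced outlines), and this package is
deliberately small-strain with tied interfaces and a parametric geometry. The
abducted run, additionally, satisfies the stopping criterion before any
element crosses the ossification threshold.

## Morphology classification

HO components use node connectivity by default (patches meeting at a vertex
read as continuous bone, as on a radiograph; edge connectivity is available).
Descriptors per component: area, femur attachment (shared node with
cortical/trabecular), skin contact fraction, signed medial offset, inertia
elongation and orientation. The published type definitions are pictorial; the
quantitative thresholds here are this package's own (versioned in
`ClassifierThresholds`): crawling = skin contact ≥ 50 % of elements and
elongation ≥ 2; attached spikes are Type 1 when medial, NONPHYSIOLOGICAL when
lateral; detached patches are Type 4 within 4 cm of an explicit wound point,
Type 5 when compact (elongation ≤ 1.8) and nearer the distal pole than the
femur tip (within 3 cm of the pole), otherwise Type 2.

## Problem sizes and determinism

Default test and acceptance runs use ~1500 tissue elements (element size
~6 mm) rather than the 5000–8000 of the source models; the mesh generator
reaches those sizes by setting `mesh_size` or `target_elements`, and all
algorithmic paths are size-independent. At ~1500 elements a full baseline run
(≈ 280 iterations) takes ~20 s on one CPU. Simulations are deterministic:
randomness exists only in the mesh-boundary jitter seed.

## Known limitations

* Small-strain linear kinematics: the femur cannot actually migrate through
  the tissue, which suppresses the load-direction-driven morphology flips
  discussed above. Soft-tissue strains near the tip reach the 0.6 clamp.
* Tied liner/socket interfaces; no frictional sliding or donning
  precompression.
* 2D coronal slice; no out-of-plane load paths.
* The ossification-probability curve between its anchors, the exact wound
  coordinates for the relocated-wound experiment, and the classifier
  thresholds are modeling choices, exposed as configuration.
* No systemic biology: hormones, hypoxia, explicit inflammation kinetics are
  out of scope; ρ_MSC is a static geometric surrogate.
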