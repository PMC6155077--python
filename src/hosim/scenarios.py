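"""Named loading scenarios and iteration schedules.

Seven experiments: upright gait loading, ±30° abducted/adducted
loading, a negative-pressure wound dressing (26.7 kPa suction over a
10 cm skin arc for 115 iterations, then upright), a tourniquet
(40 kPa inward over 3 cm arcs at mid-thigh for one iteration, then
upright), reduced skin stiffness (60 kPa), and a relocated wound site
(mid-lateral, radially decaying mesenchymal field).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from hosim.geometry import StumpMesh, CM, _ordered_boundary_chain
from hosim.materials import MaterialParams
from hosim.fe_solver import LoadCase, Support, build_load_case
from hosim.remodeling import CellField, CellFieldMode, mesenchymal_field

__all__ = [
    "Schedule",
    "SCENARIO_NAMES",
    "make_schedule",
    "iteration_to_time",
    "boundary_arc_edges",
]

SCENARIO_NAMES = (
    "upright",
    "abducted",
    "adducted",
    "negative_pressure",
    "tourniquet",
    "reduced_skin",
    "lateral_wound",
)

NEGATIVE_PRESSURE_KPA = 26.7
NEGATIVE_PRESSURE_SPAN_CM = 10.0
NEGATIVE_PRESSURE_ITERATIONS = 115
TOURNIQUET_KPA = 40.0
TOURNIQUET_SPAN_CM = 3.0
REDUCED_SKIN_KPA = 60.0
ABDUCTION_DEG = 30.0  # anticlockwise = abduction


@dataclass
class Schedule:
    """Ordered, contiguous phases of (load case, start, end iteration),
    plus material overrides and an optional wound field."""

    name: str
    phases: list[tuple[LoadCase, int, int]]
    material_overrides: dict = field(default_factory=dict)
    cell_field: CellField | None = None

    def __post_init__(self) -> None:
        expect = 1
        for _, start, end in self.phases:
            if start != expect or end < start:
                raise ValueError(
                    f"schedule '{self.name}' phases must be contiguous from iteration 1"
                )
            expect = end + 1

    def load_case_for(self, iteration: int) -> LoadCase:
        for lc, start, end in self.phases:
            if start <= iteration <= end:
                return lc
        return self.phases[-1][0]

    def end_iteration(self) -> int:
        return self.phases[-1][2]

    def apply_overrides(self, mats: MaterialParams) -> MaterialParams:
        return dc_replace(mats, **self.material_overrides)


def boundary_arc_edges(
    mesh: StumpMesh, position: str, span_cm: float
) -> np.ndarray:
    """Outer-skin boundary edges within ``span_cm`` of arc length
    centered at a named anatomical position.

    Positions: ``distal`` (lowest boundary point), ``medial`` /
    ``lateral`` (mid-height point on the +x / −x side).
    """
    edges = mesh.boundary_edges["outer_skin"]
    chain = _ordered_boundary_chain(edges)
    pts = mesh.nodes[chain]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])  # arc coordinate per chain node
    y_mid = 0.5 * (mesh.nodes[:, 1].min() + mesh.nodes[:, 1].max())
    if position == "distal":
        center_i = int(np.argmin(pts[:, 1]))
    elif position in ("medial", "lateral"):
        side = pts[:, 0] > 0 if position == "medial" else pts[:, 0] < 0
        if not side.any():
            raise ValueError(f"no boundary points on the {position} side")
        cand = np.where(side)[0]
        center_i = cand[np.argmin(np.abs(pts[cand, 1] - y_mid))]
    else:
        raise ValueError(f"unknown arc position '{position}' (distal|medial|lateral)")
    half = span_cm * CM / 2.0
    # arc coordinate of each edge midpoint via its nodes' chain positions
    pos_of = {int(n): s[i] for i, n in enumerate(chain)}
    keep = []
    for k, (a, b) in enumerate(edges):
        sa, sb = pos_of.get(int(a)), pos_of.get(int(b))
        if sa is None or sb is None:
            continue
        mid = 0.5 * (sa + sb)
        if abs(mid - s[center_i]) <= half:
            keep.append(k)
    if not keep:
        raise ValueError(f"no boundary edges within the {position} arc")
    return edges[np.array(keep)]


def make_schedule(
    name: str,
    mesh: StumpMesh,
    max_iterations: int = 1250,
    pressure_position: str = "distal",
    wound_point: tuple[float, float] | None = None,
    lateral_horizontal_sign: float = 1.0,
    abduction_sign: float = 1.0,
) -> Schedule:
    """Build one of the named scenario schedules for a mesh.

    ``pressure_position`` selects the negative-pressure dressing site;
    ``wound_point`` (mm) is required for ``lateral_wound``;
    ``abduction_sign`` flips the anticlockwise-abduction convention.
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario '{name}'; choose one of {SCENARIO_NAMES}")
    upright = build_load_case(
        mesh, 0.0, lateral_horizontal_sign=lateral_horizontal_sign, name="upright"
    )
    if name == "upright":
        return Schedule(name, [(upright, 1, max_iterations)])
    if name == "abducted":
        lc = build_load_case(
            mesh,
            abduction_sign * ABDUCTION_DEG,
            lateral_horizontal_sign=lateral_horizontal_sign,
            name="abducted",
        )
        return Schedule(name, [(lc, 1, max_iterations)])
    if name == "adducted":
        lc = build_load_case(
            mesh,
            -abduction_sign * ABDUCTION_DEG,
            lateral_horizontal_sign=lateral_horizontal_sign,
            name="adducted",
        )
        return Schedule(name, [(lc, 1, max_iterations)])
    if name == "negative_pressure":
        edges = boundary_arc_edges(mesh, pressure_position, NEGATIVE_PRESSURE_SPAN_CM)
        lc = LoadCase(
            nodal_forces=[],
            edge_pressures=[(edges, -NEGATIVE_PRESSURE_KPA * 1e-3)],  # suction, MPa
            supports=[Support(mesh.node_sets["socket_base"], 0.0, 0.0)],
            name=f"negative_pressure_{pressure_position}",
        )
        n1 = min(NEGATIVE_PRESSURE_ITERATIONS, max_iterations)
        phases = [(lc, 1, n1)]
        if max_iterations > n1:
            phases.append((upright, n1 + 1, max_iterations))
        return Schedule(name, phases)
    if name == "tourniquet":
        edges = np.concatenate(
            [
                boundary_arc_edges(mesh, "medial", TOURNIQUET_SPAN_CM),
                boundary_arc_edges(mesh, "lateral", TOURNIQUET_SPAN_CM),
            ]
        )
        lc = LoadCase(
            nodal_forces=[],
            edge_pressures=[(edges, TOURNIQUET_KPA * 1e-3)],  # inward, MPa
            supports=[Support(mesh.node_sets["socket_base"], 0.0, 0.0)],
            name="tourniquet",
        )
        phases = [(lc, 1, 1)]
        if max_iterations > 1:
            phases.append((upright, 2, max_iterations))
        return Schedule(name, phases)
    if name == "reduced_skin":
        return Schedule(
            name,
            [(upright, 1, max_iterations)],
            material_overrides={"e_skin": REDUCED_SKIN_KPA * 1e-3},  # kPa → MPa
        )
    # lateral_wound
    if wound_point is None:
        raise ValueError("scenario 'lateral_wound' requires wound_point=(x_mm, y_mm)")
    cf = mesenchymal_field(mesh, wound_point, CellFieldMode.RADIAL_FROM_POINT)
    return Schedule(name, [(upright, 1, max_iterations)], cell_field=cf)


HOURS_PER_ITERATION = 5 * 30.44 * 24 / 1250.0  # 1250 iterations ≡ ~5 months


def iteration_to_time(iteration: int) -> dict[str, float]:
    """Approximate elapsed wall time for logging (1250 iterations maps
    to about five months, so one iteration is just under 3 hours)."""
    hours = iteration * HOURS_PER_ITERATION
    return {
        "hours": hours,
        "days": hours / 24.0,
        "months": hours / (30.44 * 24.0),
    }
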