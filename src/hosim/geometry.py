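"""Parametric 2D residual-limb (stump) geometry and triangulation.

The generator builds a coronal-plane cross-section of a trans-femoral
residual limb: a residual femur (trabecular core inside a cortical
shell) embedded in soft tissue with a rounded distal cap, the outermost
soft-tissue layer re-tagged as skin, and optionally a liner band and a
rigid socket band wrapped outside the skin.  All coordinates are stored
in mm; the public parameter object is in cm (the convention of the
clinical measurements it mirrors).

Meshing strategy: the nested region outlines (outer skin surface,
cortical surface, trabecular surface) are sampled at the target element
size, an interior point lattice is laid down away from the interfaces,
and the point cloud is Delaunay-triangulated; triangles are classified
by centroid containment.  The outlines are convex by construction, so
the Delaunay triangulation conforms to them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import Delaunay, cKDTree
from scipy.optimize import brentq
from shapely.geometry import LineString, Polygon, box

from hosim.materials import TissueClass

__all__ = [
    "StumpParams",
    "StumpMesh",
    "GeometryError",
    "generate_stump_mesh",
    "tag_skin_layer",
    "element_geometry",
    "measure_femur_width",
    "measure_femoral_alignment",
    "mirror_mesh",
]

CM = 10.0  # mm per cm


class GeometryError(ValueError):
    """Raised for infeasible stump geometry."""


@dataclass(frozen=True)
class StumpParams:
    """Parametric description of a synthetic stump model (lengths in cm).

    Defaults follow the first of the three published stump geometries:
    femur 2.7 cm wide at mid-shaft, proximal limb width 13.8 cm, limb
    length 20.5 cm, 205 cm² of soft tissue, femur tilted 10° from
    vertical, 5 cm of soft tissue distal to the femur tip.
    """

    femur_width_midshaft: float = 2.7
    proximal_width: float = 13.8
    stump_length: float = 20.5
    soft_tissue_area_target: float | None = 205.0
    femoral_alignment: float = 10.0  # degrees from vertical, + tilts tip medially
    distal_soft_tissue_depth: float = 5.0
    cortical_shell_thickness: float = 0.45
    skin_thickness: float = 0.25
    mesh_size: float = 0.3
    target_elements: int | None = None  # overrides mesh_size when set
    include_liner_socket: bool = True
    liner_thickness: float = 0.6
    socket_thickness: float = 1.2
    socket_base_span: float = 3.5  # cm of fixed arc at the distal pole
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.femur_width_midshaft < self.proximal_width:
            raise GeometryError("femur must be narrower than the proximal limb width")
        if not self.stump_length > self.distal_soft_tissue_depth > 0:
            raise GeometryError("need stump_length > distal_soft_tissue_depth > 0")
        if self.skin_thickness <= 0 or self.mesh_size <= 0:
            raise GeometryError("skin_thickness and mesh_size must be positive")
        if not 3.0 <= self.socket_base_span * CM / CM <= 4.0:
            raise GeometryError("socket_base_span must lie in [3, 4] cm")
        if 2 * self.cortical_shell_thickness >= self.femur_width_midshaft:
            raise GeometryError("cortical shell leaves no trabecular core")


@dataclass
class StumpMesh:
    """Conforming triangle mesh with tissue-region tags (coordinates mm).

    ``boundary_edges`` holds named edge sets as (n, 2) node-index arrays:
    ``outer_skin`` (the skin surface), ``proximal_cut`` (the amputation
    plane at the top), ``outer_ring`` (outermost boundary — socket
    surface when a socket is present, else the skin surface) and
    ``socket_base`` (the distally fixed arc).  ``node_sets`` holds
    ``proximal_cortical_medial`` / ``proximal_cortical_lateral`` (load
    application bands).
    """

    nodes: np.ndarray  # (n_nodes, 2) float, mm
    triangles: np.ndarray  # (n_elem, 3) int
    element_region: np.ndarray  # (n_elem,) int (TissueClass values)
    boundary_edges: dict[str, np.ndarray] = field(default_factory=dict)
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    medial_lateral_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))
    femoral_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0]))
    params: StumpParams | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    def region_mask(self, *classes: TissueClass) -> np.ndarray:
        return np.isin(self.element_region, [int(c) for c in classes])

    def copy(self) -> "StumpMesh":
        return StumpMesh(
            nodes=self.nodes.copy(),
            triangles=self.triangles.copy(),
            element_region=self.element_region.copy(),
            boundary_edges={k: v.copy() for k, v in self.boundary_edges.items()},
            node_sets={k: v.copy() for k, v in self.node_sets.items()},
            medial_lateral_axis=self.medial_lateral_axis.copy(),
            femoral_axis=self.femoral_axis.copy(),
            params=self.params,
        )


# ---------------------------------------------------------------------------
# element geometry


def element_geometry(mesh: StumpMesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-element centroids (mm) and positive areas (mm²)."""
    p = mesh.nodes[mesh.triangles]  # (m, 3, 2)
    centroids = p.mean(axis=1)
    v1 = p[:, 1] - p[:, 0]
    v2 = p[:, 2] - p[:, 0]
    areas = 0.5 * (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])
    return centroids, areas


def _orient_ccw(nodes: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Flip triangles with negative signed area to counter-clockwise."""
    p = nodes[triangles]
    v1 = p[:, 1] - p[:, 0]
    v2 = p[:, 2] - p[:, 0]
    neg = (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]) < 0
    out = triangles.copy()
    out[neg] = out[neg][:, [0, 2, 1]]
    return out


def boundary_edge_array(triangles: np.ndarray) -> np.ndarray:
    """Edges used by exactly one triangle, as (n, 2) ordered pairs."""
    edges = np.concatenate(
        [triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]]
    )
    key = np.sort(edges, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    return edges[idx[counts == 1]]


# ---------------------------------------------------------------------------
# outline construction


def _outline_polygon(params: StumpParams, cap_halfwidth_mm: float) -> Polygon:
    """Stump outline: the convex envelope of the proximal cut segment and
    a distal cap circle (tangent sides), with a gentle barrel bulge.

    The bulge keeps every sampled side point strictly convex — exactly
    collinear boundary samples degrade the Delaunay boundary into long
    chords — and rounds the profile the way a fleshy limb tapers.
    """
    L = params.stump_length * CM
    wp = params.proximal_width * CM / 2.0
    a = cap_halfwidth_mm
    center = np.array([0.0, a])
    corner = np.array([wp, L])
    d = corner - center
    dist = np.linalg.norm(d)
    if dist <= a:
        raise GeometryError("distal cap radius exceeds the proximal corner reach")
    phi = np.arctan2(d[1], d[0])
    alpha = np.arccos(a / dist)
    th_med = phi - alpha  # tangent-point angle on the medial side
    t_med = center + a * np.array([np.cos(th_med), np.sin(th_med)])
    bulge = 0.02 * wp
    n_side = 160

    def side(corner_pt: np.ndarray, tangent_pt: np.ndarray, outward: np.ndarray):
        ts = np.linspace(0.0, 1.0, n_side + 1)[:, None]
        line = corner_pt + ts * (tangent_pt - corner_pt)
        return line + outward * (bulge * 4.0 * ts * (1.0 - ts))

    out_med = np.array([np.cos(th_med + alpha - np.pi / 2), np.sin(th_med + alpha - np.pi / 2)])
    # outward normal of the straight side = radial direction at the tangent point
    out_med = (t_med - center) / a
    pts: list[tuple[float, float]] = [(-wp, L)]
    # lateral side down (mirror of the medial side)
    for q in side(corner, t_med, out_med)[1:-1]:
        pts.append((-q[0], q[1]))
    # cap arc from the lateral tangent point through the bottom to the medial
    th_lat = np.pi - th_med
    n_arc = 80
    for th in np.linspace(th_lat - 2 * np.pi, th_med, n_arc + 1):
        pts.append(tuple(center + a * np.array([np.cos(th), np.sin(th)])))
    # medial side up
    for q in side(corner, t_med, out_med)[-2::-1]:
        pts.append(tuple(q))
    return Polygon(pts).buffer(0)


def _femur_polygons(params: StumpParams) -> tuple[Polygon, Polygon, np.ndarray, np.ndarray]:
    """Cortical outer and trabecular inner outlines, plus the femoral
    axis unit vector and the proximal axis point."""
    L = params.stump_length * CM
    theta = np.deg2rad(params.femoral_alignment)
    d = np.array([np.sin(theta), -np.cos(theta)])  # down the shaft, + tilts medially
    tip_y = params.distal_soft_tissue_depth * CM
    r_out = params.femur_width_midshaft * CM / 2.0
    # keep the shaft roughly centered: shift the proximal point by half
    # the horizontal run of the tilted axis
    run = (L - tip_y) * np.tan(theta)
    top = np.array([-run / 2.0, L])
    length = (L - tip_y) / np.cos(theta)
    tip_center = top + d * (length - r_out)  # tip arc center, surface at tip_y
    axis_hi = top - d * (2 * r_out)  # extend above the cut, clipped below
    cortical = LineString([axis_hi, tip_center]).buffer(r_out, quad_segs=24)
    cortical = cortical.intersection(box(-1e6, -1e6, 1e6, L))
    r_in = r_out - params.cortical_shell_thickness * CM
    trabecular = LineString([axis_hi, tip_center + d * (r_out - r_in) * 0.0]).buffer(
        r_in, quad_segs=24
    )
    trab_tip = top + d * (length - r_out - params.cortical_shell_thickness * CM + r_in)
    trabecular = LineString([axis_hi, trab_tip - d * r_in]).buffer(r_in, quad_segs=24)
    trabecular = trabecular.intersection(box(-1e6, -1e6, 1e6, L))
    return cortical, trabecular, -d, top


def _sample_ring(ring, spacing: float, phase: float = 0.0) -> np.ndarray:
    """Points along a closed shapely ring at roughly uniform arc spacing."""
    total = ring.length
    n = max(8, int(round(total / spacing)))
    s = (np.arange(n) / n + phase) % 1.0
    return np.array([ring.interpolate(si * total).coords[0] for si in np.sort(s)])


def _dedupe(points: np.ndarray, tol: float) -> np.ndarray:
    """Greedy removal of points closer than tol to an earlier point."""
    tree = cKDTree(points)
    pairs = tree.query_pairs(tol, output_type="ndarray")
    drop = np.zeros(len(points), dtype=bool)
    for i, j in pairs:
        hi = max(i, j)
        lo = min(i, j)
        if not drop[lo]:
            drop[hi] = True
    return points[~drop]


# ---------------------------------------------------------------------------
# generator


def generate_stump_mesh(params: StumpParams) -> StumpMesh:
    """Generate the parametric stump mesh.

    Deterministic for a fixed seed (the seed jitters only the phase of
    the boundary sampling).  Raises :class:`GeometryError` for
    infeasible inputs (femur wider than the outline, skin thicker than
    the soft-tissue annulus).
    """
    rng = np.random.default_rng(params.seed)
    L = params.stump_length * CM
    cortical, trabecular, femoral_axis, _top = _femur_polygons(params)

    # distal cap half-width: solve for the soft-tissue area target
    wp = params.proximal_width * CM / 2.0
    lo_a, hi_a = 0.2 * wp, 0.98 * wp

    def soft_area_cm2(a_mm: float) -> float:
        outline = _outline_polygon(params, a_mm)
        return (outline.area - outline.intersection(cortical).area) / CM**2

    if params.soft_tissue_area_target is not None:
        target = params.soft_tissue_area_target
        f_lo = soft_area_cm2(lo_a) - target
        f_hi = soft_area_cm2(hi_a) - target
        if f_lo * f_hi > 0:
            raise GeometryError(
                f"soft-tissue area target {target} cm² unreachable "
                f"(range {f_lo + target:.0f}–{f_hi + target:.0f} cm²)"
            )
        a = brentq(lambda x: soft_area_cm2(x) - target, lo_a, hi_a, xtol=1e-3)
    else:
        a = 0.5 * wp
    outline = _outline_polygon(params, a)

    # the femur meets the proximal cut plane, so only its lateral/distal
    # surface needs a skin margin
    margin = params.skin_thickness * CM
    cort_below_cut = cortical.intersection(box(-1e6, -1e6, 1e6, L - 3 * margin))
    if not outline.buffer(-margin).contains(cort_below_cut):
        raise GeometryError("femur does not fit inside the outline with a skin margin")

    h = params.mesh_size * CM
    if params.target_elements is not None:
        # equilateral-area estimate: n ≈ A / (√3/4 h²)
        h = float(np.sqrt(4.0 * outline.area / (np.sqrt(3.0) * params.target_elements)))

    phase = rng.uniform(0.0, 0.2)
    ring_pts = [
        _sample_ring(outline.exterior, h, phase),
        _sample_ring(cortical.exterior, h, rng.uniform(0.0, 0.2)),
        _sample_ring(trabecular.exterior, h, rng.uniform(0.0, 0.2)),
    ]
    bnd = _dedupe(np.concatenate(ring_pts), 0.35 * h)

    # interior hex lattice, kept clear of the interfaces
    minx, miny, maxx, maxy = outline.bounds
    rows = np.arange(miny + 0.4 * h, maxy, h * np.sqrt(3) / 2.0)
    pts = []
    for k, y in enumerate(rows):
        xs = np.arange(minx, maxx + h, h) + (0.5 * h if k % 2 else 0.0)
        pts.append(np.column_stack([xs, np.full_like(xs, y)]))
    lattice = np.concatenate(pts)
    inside = shapely.contains_xy(outline, lattice[:, 0], lattice[:, 1])
    lattice = lattice[inside]
    d_bnd, _ = cKDTree(bnd).query(lattice)
    lattice = lattice[d_bnd > 0.6 * h]

    points = np.concatenate([bnd, lattice])
    tri = Delaunay(points)
    cent = points[tri.simplices].mean(axis=1)
    keep = shapely.contains_xy(outline.buffer(0.05 * h), cent[:, 0], cent[:, 1])
    # drop slivers (collinear boundary chains can create them)
    p = points[tri.simplices]
    areas2 = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 1, 1] - p[:, 0, 1]
    ) * (p[:, 2, 0] - p[:, 0, 0])
    keep &= np.abs(areas2) > 1e-3 * h**2
    triangles = tri.simplices[keep]

    # compact node numbering
    used = np.unique(triangles)
    remap = -np.ones(len(points), dtype=int)
    remap[used] = np.arange(len(used))
    nodes = points[used]
    triangles = _orient_ccw(nodes, remap[triangles])

    cent = nodes[triangles].mean(axis=1)
    region = np.full(len(triangles), int(TissueClass.SOFT))
    in_cort = shapely.contains_xy(cortical, cent[:, 0], cent[:, 1])
    in_trab = shapely.contains_xy(trabecular, cent[:, 0], cent[:, 1])
    region[in_cort] = int(TissueClass.CORTICAL)
    region[in_trab] = int(TissueClass.TRABECULAR)

    mesh = StumpMesh(
        nodes=nodes,
        triangles=triangles,
        element_region=region,
        medial_lateral_axis=np.array([1.0, 0.0]),
        femoral_axis=femoral_axis,
        params=params,
    )
    _build_boundary_sets(mesh, L)
    tag_skin_layer(mesh, inplace=True)
    if params.include_liner_socket:
        _add_liner_socket(mesh, params)
    _build_support_and_load_sets(mesh, params)
    return mesh


def _build_boundary_sets(mesh: StumpMesh, top_y: float) -> None:
    edges = boundary_edge_array(mesh.triangles)
    mid = mesh.nodes[edges].mean(axis=1)
    on_top = mid[:, 1] > top_y - 1e-6
    mesh.boundary_edges["proximal_cut"] = edges[on_top]
    mesh.boundary_edges["outer_skin"] = edges[~on_top]
    mesh.boundary_edges["outer_ring"] = edges[~on_top]


def tag_skin_layer(mesh: StumpMesh, inplace: bool = False) -> StumpMesh:
    """Re-tag the outermost soft-tissue layer as skin.

    A SOFT element becomes SKIN if it has an edge on the outer skin
    boundary or its centroid lies within the skin thickness of it.
    """
    if not inplace:
        mesh = mesh.copy()
    if "outer_skin" not in mesh.boundary_edges or len(mesh.boundary_edges["outer_skin"]) == 0:
        raise GeometryError("mesh has no outer_skin boundary set")
    soft = mesh.element_region == int(TissueClass.SOFT)
    if not soft.any():
        raise GeometryError("mesh has no SOFT elements to tag as skin")
    edges = mesh.boundary_edges["outer_skin"]
    bnd_nodes = np.unique(edges)
    on_bnd = np.isin(mesh.triangles, bnd_nodes).sum(axis=1) >= 2
    thick = (mesh.params.skin_thickness * CM) if mesh.params else 2.5
    cent, _ = element_geometry(mesh)
    # distance to the boundary polyline, approximated by edge midpoints+nodes
    samples = np.concatenate([mesh.nodes[bnd_nodes], mesh.nodes[edges].mean(axis=1)])
    d, _ = cKDTree(samples).query(cent)
    skin = soft & (on_bnd | (d < thick))
    mesh.element_region[skin] = int(TissueClass.SKIN)
    return mesh


def _ordered_boundary_chain(edges: np.ndarray) -> np.ndarray:
    """Order an open boundary edge set into a node chain."""
    from collections import defaultdict

    adj = defaultdict(list)
    for a, b in edges:
        adj[int(a)].append(int(b))
        adj[int(b)].append(int(a))
    ends = [n for n, nb in adj.items() if len(nb) == 1]
    start = min(ends) if ends else int(edges[0, 0])
    chain = [start]
    prev = None
    while True:
        nxt = [n for n in adj[chain[-1]] if n != prev]
        if not nxt:
            break
        prev = chain[-1]
        chain.append(nxt[0])
        if chain[-1] == start:
            break
        if len(chain) > len(edges) + 2:
            break
    return np.array(chain)


def _add_liner_socket(mesh: StumpMesh, params: StumpParams) -> None:
    """Wrap liner and socket bands outside the skin surface.

    Built as structured strips sharing the skin boundary nodes (tied
    interfaces, no sliding contact).
    """
    h = np.median(
        np.linalg.norm(
            mesh.nodes[mesh.boundary_edges["outer_skin"][:, 0]]
            - mesh.nodes[mesh.boundary_edges["outer_skin"][:, 1]],
            axis=1,
        )
    )
    chain = _ordered_boundary_chain(mesh.boundary_edges["outer_skin"])
    # order medial→distal→lateral consistently: start at the +x top corner
    if mesh.nodes[chain[0], 0] < mesh.nodes[chain[-1], 0]:
        chain = chain[::-1]
    pts = mesh.nodes[chain]
    # outward normals (polygon interior is to the left of the CCW chain)
    tang = np.gradient(pts, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    normals = np.column_stack([tang[:, 1], -tang[:, 0]])
    cent_all = mesh.nodes.mean(axis=0)
    flip = ((pts - cent_all) * normals).sum() < 0
    if flip:
        normals = -normals

    specs = [
        (params.liner_thickness * CM, TissueClass.LINER),
        (params.socket_thickness * CM, TissueClass.SOCKET),
    ]
    nodes = mesh.nodes
    tris = [mesh.triangles]
    regions = [mesh.element_region]
    inner_ring = chain
    offset = 0.0
    for thickness, cls in specs:
        n_layers = max(1, int(round(thickness / h)))
        for k in range(n_layers):
            offset += thickness / n_layers
            new_pts = pts + normals * offset
            new_idx = np.arange(len(nodes), len(nodes) + len(new_pts))
            nodes = np.concatenate([nodes, new_pts])
            a, b = inner_ring[:-1], inner_ring[1:]
            c, d = new_idx[:-1], new_idx[1:]
            strip = np.concatenate(
                [np.column_stack([a, b, d]), np.column_stack([a, d, c])]
            )
            tris.append(strip)
            regions.append(np.full(len(strip), int(cls)))
            inner_ring = new_idx
    mesh.nodes = nodes
    mesh.triangles = _orient_ccw(nodes, np.concatenate(tris))
    mesh.element_region = np.concatenate(regions)
    outer_ring_edges = np.column_stack([inner_ring[:-1], inner_ring[1:]])
    mesh.boundary_edges["outer_ring"] = outer_ring_edges


def _build_support_and_load_sets(mesh: StumpMesh, params: StumpParams) -> None:
    # socket_base: outermost-ring edges within the base arc of the distal pole
    edges = mesh.boundary_edges["outer_ring"]
    mid = mesh.nodes[edges].mean(axis=1)
    pole = mesh.nodes[np.argmin(mesh.nodes[:, 1])]
    half_span = params.socket_base_span * CM / 2.0
    near = np.linalg.norm(mid - pole, axis=1) <= half_span
    if not near.any():
        raise GeometryError("no boundary edges near the distal pole for the base support")
    mesh.boundary_edges["socket_base"] = edges[near]
    mesh.node_sets["socket_base"] = np.unique(edges[near])

    # proximal cortical load bands (1 cm deep), split medial/lateral
    L = params.stump_length * CM
    cort_elems = mesh.element_region == int(TissueClass.CORTICAL)
    cort_nodes = np.unique(mesh.triangles[cort_elems])
    p = mesh.nodes[cort_nodes]
    band = cort_nodes[p[:, 1] > L - 1.0 * CM]
    if len(band) == 0:
        raise GeometryError("no proximal cortical nodes found for load application")
    pb = mesh.nodes[band]
    center_x = pb[:, 0].mean()
    xi = (pb[:, 0] - center_x) * mesh.medial_lateral_axis[0]
    medial = band[xi > 0]
    lateral = band[xi <= 0]
    if len(medial) == 0 or len(lateral) == 0:
        raise GeometryError("could not split proximal cortical band into medial/lateral")
    mesh.node_sets["proximal_cortical_medial"] = medial
    mesh.node_sets["proximal_cortical_lateral"] = lateral


# ---------------------------------------------------------------------------
# measurements (used by tests and reports)


def measure_femur_width(mesh: StumpMesh) -> float:
    """Femur width (cm) at mid-shaft, perpendicular to the femoral axis."""
    femur = mesh.region_mask(TissueClass.CORTICAL, TissueClass.TRABECULAR)
    cent, _ = element_geometry(mesh)
    c = cent[femur]
    axis = mesh.femoral_axis / np.linalg.norm(mesh.femoral_axis)
    perp = np.array([-axis[1], axis[0]])
    s = c @ axis
    mid = 0.5 * (s.min() + s.max())
    band = np.abs(s - mid) < 5.0  # ±5 mm of mid-shaft
    nodes = np.unique(mesh.triangles[np.where(femur)[0][band]])
    q = mesh.nodes[nodes] @ perp
    return float((q.max() - q.min()) / CM)


def measure_femoral_alignment(mesh: StumpMesh) -> float:
    """Femoral axis angle from vertical (degrees), from the principal
    axis of the femur element centroids."""
    femur = mesh.region_mask(TissueClass.CORTICAL, TissueClass.TRABECULAR)
    cent, areas = element_geometry(mesh)
    c = cent[femur]
    w = areas[femur]
    mu = np.average(c, weights=w, axis=0)
    d = c - mu
    cov = (d * w[:, None]).T @ d / w.sum()
    vals, vecs = np.linalg.eigh(cov)
    axis = vecs[:, np.argmax(vals)]
    if axis[1] < 0:
        axis = -axis
    # positive alignment = distal tip tilted medially (+x)
    return float(np.rad2deg(np.arctan2(-axis[0], axis[1])))


def mirror_mesh(mesh: StumpMesh) -> StumpMesh:
    """Mirror the mesh about the vertical axis (medial↔lateral)."""
    out = mesh.copy()
    out.nodes[:, 0] *= -1.0
    out.triangles = out.triangles[:, [0, 2, 1]]  # restore CCW orientation
    out.medial_lateral_axis = mesh.medial_lateral_axis.copy()
    out.femoral_axis = mesh.femoral_axis * np.array([-1.0, 1.0])
    swap = {
        "proximal_cortical_medial": "proximal_cortical_lateral",
        "proximal_cortical_lateral": "proximal_cortical_medial",
    }
    out.node_sets = {swap.get(k, k): v.copy() for k, v in mesh.node_sets.items()}
    return out
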