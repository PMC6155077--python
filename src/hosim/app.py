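"""Run configuration, end-to-end driver and built-in fixtures."""

from __future__ import annotations

import csv
import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from hosim.geometry import StumpMesh, StumpParams, generate_stump_mesh
from hosim.materials import MaterialParams, TissueClass
from hosim.meshio import SeriesWriter, read_mesh
from hosim.morphology import classify, extract_ho
from hosim.remodeling import RemodelParams, run_simulation
from hosim.scenarios import make_schedule

__all__ = ["RunConfig", "load_config", "run_from_config", "make_fixtures"]


@dataclass
class RunConfig:
    """Full description of one simulation run (serializable)."""

    mesh_source: str = "generate"  # generate | file
    mesh_path: str | None = None
    stump: dict = field(default_factory=dict)  # StumpParams overrides
    materials: dict = field(default_factory=dict)  # MaterialParams overrides
    remodeling: dict = field(default_factory=dict)  # RemodelParams overrides
    scenario: str = "upright"
    scenario_options: dict = field(default_factory=dict)
    max_iterations: int = 1250
    snapshot_stride: int = 0
    plane: str = "stress"
    output_dir: str = "results"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path_or_dict) -> RunConfig:
    """Load a YAML/JSON config; unknown keys are rejected."""
    if isinstance(path_or_dict, dict):
        data = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}; known: {sorted(known)}")
    for sub, cls in (("stump", StumpParams), ("remodeling", RemodelParams)):
        if sub in data and data[sub]:
            sub_known = {f.name for f in dataclasses.fields(cls)}
            bad = set(data[sub]) - sub_known
            if bad:
                raise ValueError(f"unknown keys in '{sub}': {sorted(bad)}")
    return RunConfig(**data)


def _build_mesh(cfg: RunConfig) -> StumpMesh:
    if cfg.mesh_source == "file":
        if not cfg.mesh_path:
            raise ValueError("mesh_source 'file' requires mesh_path")
        return read_mesh(cfg.mesh_path)
    params = StumpParams(**{"seed": cfg.seed, **cfg.stump})
    return generate_stump_mesh(params)


def run_from_config(cfg: RunConfig, progress: bool = False):
    """Execute generate/read → schedule → simulate → classify.

    Writes a VTU snapshot series, a CSV iteration log, a morphology
    report (JSON) and an echo of the configuration for provenance.
    Returns (mesh, state, report).
    """
    os.makedirs(cfg.output_dir, exist_ok=True)
    mesh = _build_mesh(cfg)
    mats = MaterialParams(**cfg.materials) if cfg.materials else MaterialParams()
    params = (
        RemodelParams(**{"max_iterations": cfg.max_iterations, **cfg.remodeling})
        if cfg.remodeling or cfg.max_iterations
        else RemodelParams()
    )
    schedule = make_schedule(
        cfg.scenario, mesh, max_iterations=params.max_iterations, **cfg.scenario_options
    )
    log_rows: list = []
    state = run_simulation(
        mesh,
        schedule,
        params=params,
        snapshot_stride=cfg.snapshot_stride,
        mats=mats,
        plane=cfg.plane,
        progress=progress,
        log_rows=log_rows,
    )

    writer = SeriesWriter(cfg.output_dir)
    for it, rho, tissue in state.snapshots:
        writer.save(mesh, it, {"density": rho, "tissue": tissue.astype(np.int64)})
    writer.save(
        mesh,
        state.iteration,
        {
            "density": state.rho,
            "tissue": state.tissue.astype(np.int64),
            "sed": state.sed,
            "modulus_mpa": state.e_elements,
        },
    )
    with open(os.path.join(cfg.output_dir, "run_log.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["iteration", "mean_abs_drho", "ho_area_cm2", "fe_subiterations"])
        for row in log_rows:
            w.writerow([row[0], f"{row[1]:.12e}", f"{row[2]:.6f}", row[3]])

    wound = None
    if schedule.cell_field is not None:
        wound = schedule.cell_field.wound_point
    comps = extract_ho(mesh, state.tissue, state.rho)
    report = classify(mesh, comps, wound_point=wound)
    report.to_json(os.path.join(cfg.output_dir, "morphology.json"))
    with open(os.path.join(cfg.output_dir, "config_echo.json"), "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=2, default=str)
    return mesh, state, report


# ---------------------------------------------------------------------------
# fixtures


def square_mesh(n: int = 4, size: float = 1.0) -> StumpMesh:
    """n×n structured triangulation of a [0, size]² square (all SOFT)."""
    xs = np.linspace(0.0, size, n + 1)
    xx, yy = np.meshgrid(xs, xs)
    nodes = np.column_stack([xx.ravel(), yy.ravel()])
    tris = []
    for j in range(n):
        for i in range(n):
            a = j * (n + 1) + i
            b = a + 1
            c = a + n + 1
            d = c + 1
            tris.append([a, b, d])
            tris.append([a, d, c])
    tris = np.array(tris, dtype=int)
    return StumpMesh(
        nodes=nodes,
        triangles=tris,
        element_region=np.full(len(tris), int(TissueClass.SOFT)),
    )


def strip_mesh(length: float, height: float, nx: int, ny: int) -> StumpMesh:
    """Structured cantilever strip [0,length]×[0,height]."""
    xs = np.linspace(0.0, length, nx + 1)
    ys = np.linspace(0.0, height, ny + 1)
    xx, yy = np.meshgrid(xs, ys)
    nodes = np.column_stack([xx.ravel(), yy.ravel()])
    tris = []
    for j in range(ny):
        for i in range(nx):
            a = j * (nx + 1) + i
            b = a + 1
            c = a + nx + 1
            d = c + 1
            tris.append([a, b, d])
            tris.append([a, d, c])
    tris = np.array(tris, dtype=int)
    return StumpMesh(
        nodes=nodes,
        triangles=tris,
        element_region=np.full(len(tris), int(TissueClass.CORTICAL)),
    )


def mini_stump(n_elements: int = 300, seed: int = 0, **overrides) -> StumpMesh:
    """Small stump fixture for fast end-to-end tests."""
    kw = dict(
        target_elements=n_elements,
        soft_tissue_area_target=205.0,
        seed=seed,
    )
    kw.update(overrides)
    return generate_stump_mesh(StumpParams(**kw))


def make_fixtures() -> dict:
    """Analytic FE fixtures, a mini stump, and synthetic HO-shape
    fixtures for the classifier (tissue arrays on the mini stump)."""
    stump = mini_stump()
    return {
        "patch": square_mesh(4),
        "cantilever": strip_mesh(100.0, 10.0, 40, 4),
        "mini_stump": stump,
    }
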