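import numpy as np
import pytest

from hosim.app import mini_stump, square_mesh, strip_mesh
from hosim.geometry import StumpParams, generate_stump_mesh, element_geometry
from hosim.materials import TissueClass
from hosim.remodeling import RemodelParams, run_simulation
from hosim.scenarios import make_schedule


@pytest.fixture(scope="session")
def model1_mesh():
    """Scaled-down baseline stump (first published geometry, ~1500
    target elements)."""
    return generate_stump_mesh(StumpParams(target_elements=1500))


@pytest.fixture(scope="session")
def mini_mesh():
    """~450-element stump for fast end-to-end runs."""
    return mini_stump(300)


@pytest.fixture(scope="session")
def patch():
    return square_mesh(4, 1.0)


@pytest.fixture(scope="session")
def cantilever():
    return strip_mesh(100.0, 10.0, 60, 6)


@pytest.fixture(scope="session")
def baseline_run(model1_mesh):
    """Upright-loading baseline simulation run to its stopping criterion
    (shared by the morphology and convergence checks)."""
    sched = make_schedule("upright", model1_mesh, max_iterations=1250)
    state = run_simulation(model1_mesh, sched, RemodelParams(max_iterations=1250))
    return state


def paint_tissue(mesh, selector):
    """Return a tissue array with SOFT elements satisfying ``selector``
    (a boolean mask over elements) re-tagged HO."""
    tissue = mesh.element_region.copy()
    soft = tissue == int(TissueClass.SOFT)
    tissue[soft & selector] = int(TissueClass.HO)
    return tissue


@pytest.fixture(scope="session")
def geom(model1_mesh):
    cent, areas = element_geometry(model1_mesh)
    femur = model1_mesh.region_mask(TissueClass.CORTICAL, TissueClass.TRABECULAR)
    tip = cent[femur][np.argmin(cent[femur][:, 1])]
    skin_nodes = np.unique(model1_mesh.boundary_edges["outer_skin"])
    pole = model1_mesh.nodes[skin_nodes[np.argmin(model1_mesh.nodes[skin_nodes, 1])]]
    return {"cent": cent, "areas": areas, "tip": tip, "pole": pole}
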