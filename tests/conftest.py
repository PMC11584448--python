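import numpy as np
import pytest

import breastfem as bf


@pytest.fixture(scope="session")
def materials():
    return bf.material_table()


@pytest.fixture(scope="session")
def default_mesh():
    """Default-parameter synthetic anatomy."""
    return bf.build_anatomy()


@pytest.fixture(scope="session")
def coarse_mesh():
    """Desk-scale mesh for dynamic tests (~2-3k tets)."""
    return bf.build_anatomy(bf.AnatomyParams(mesh_size_fine=14.0,
                                             mesh_size_coarse=22.0))


@pytest.fixture(scope="session")
def coarse_static(coarse_mesh, materials):
    """Gravity equilibrium on the coarse mesh, shared by dynamic tests."""
    bcs = bf.BoundaryConditions.from_mesh(coarse_mesh)
    model = bf.FEModel(coarse_mesh, materials)
    res = bf.solve_static(coarse_mesh, materials, bcs, model=model)
    return {"bcs": bcs, "model": model, "result": res}


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
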