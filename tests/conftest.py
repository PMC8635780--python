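import numpy as np
import pytest

from corticovar import synthetic


@pytest.fixture(scope="session")
def small_mesh():
    return synthetic.make_toy_surface(subdivisions=3, radius=50.0)


@pytest.fixture(scope="session")
def cohort_meta():
    return synthetic.make_cohort_meta(11, 24, seed=1)


@pytest.fixture(scope="session")
def region_table(cohort_meta):
    return synthetic.simulate_region_table(cohort_meta, seed=5)


@pytest.fixture(scope="session")
def thickness_dataset(small_mesh, cohort_meta):
    mesh = small_mesh
    d = np.linalg.norm(mesh.vertices - mesh.vertices[100], axis=1)
    patch = np.where(d < 12)[0]
    ds = synthetic.simulate_thickness_dataset(
        mesh, cohort_meta, effect_patches=[(patch, 0.45)], noise_sd=0.15,
        seed=3)
    ds.injected_patch = patch
    return ds


@pytest.fixture(scope="session")
def bold_cohort():
    meta = synthetic.make_cohort_meta(11, 15, seed=1)
    return synthetic.simulate_bold_cohort(meta, n_volumes=200, seed=2)
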