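import numpy as np
import pytest

from lungreg import (PointCloud, SyntheticPairSpec, estimate_normals,
                     make_registration_pair)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def sphere_cloud():
    """2000 quasi-uniform points on the unit sphere, with exact ids."""
    g = np.random.default_rng(7)
    u = g.standard_normal((2000, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    return PointCloud(u, ids=np.arange(2000))


@pytest.fixture(scope="session")
def small_pair():
    """Small non-corresponding sliding-motion pair for loop-level tests."""
    spec = SyntheticPairSpec(n_dense=2000, n_source=300, n_target=600,
                             corresponding=False, field_kind="sliding",
                             amplitude=5.0, seed=42)
    return make_registration_pair(spec)


@pytest.fixture(scope="session")
def shell_with_normals():
    """A lung-like shell with normals, used as a self-registration target."""
    from lungreg import make_lung_surface

    cloud = make_lung_surface(800, seed=5)
    return estimate_normals(cloud, k=12)


def random_correspondences(g, n, weights=None):
    """Random correspondence set with unit normals, for energy oracles."""
    from lungreg.geometry import CorrespondenceSet

    u = g.standard_normal((n, 3))
    nrm = g.standard_normal((n, 3))
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    w = np.ones(n) if weights is None else weights
    return CorrespondenceSet(target_points=u, target_normals=nrm, weights=w,
                             distances=np.zeros(n))
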