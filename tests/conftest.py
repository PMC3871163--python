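import numpy as np
import pytest
from hypothesis import settings

from pestsamp import SiteSample, SyntheticConfig, TreeRecord, generate_site

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


def make_site(pcts, coords=None, site_id="toy"):
    """Site from explicit percent values (and optional coordinates)."""
    n = len(pcts)
    if coords is None:
        coords = [(10.0 * i, 0.0) for i in range(n)]
    trees = [
        TreeRecord(
            tree_id=f"T{i + 1:03d}",
            east=float(coords[i][0]),
            north=float(coords[i][1]),
            pct_galled=float(pcts[i]),
            collection_index=i + 1,
        )
        for i in range(n)
    ]
    return SiteSample(site_id=site_id, trees=trees)


@pytest.fixture(scope="session")
def iid_site():
    """200-tree spatially independent NB(mu=4, k=1) site."""
    cfg = SyntheticConfig(nx=20, ny=10, mu=4.0, k=1.0, corr_range=0.0, seed=0)
    return generate_site(cfg, site_id="iid")


@pytest.fixture(scope="session")
def g_analogue():
    """Synthetic analogue of the deposited low-density site: N=200,
    mean percent galling 1.80, k=0.73, spatially independent."""
    cfg = SyntheticConfig(nx=20, ny=10, mu=1.80, k=0.73, corr_range=0.0, seed=0)
    return generate_site(cfg, site_id="G")


@pytest.fixture(scope="session")
def g_analogue_spatial():
    """Autocorrelated variant of the low-density analogue (range = half the
    long axis, weakly structured latent field)."""
    cfg = SyntheticConfig(nx=20, ny=10, mu=1.80, k=0.73, corr_range=95.0, seed=0)
    return generate_site(cfg, site_id="G_sp")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
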