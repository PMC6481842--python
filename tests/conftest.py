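import numpy as np
import pandas as pd
import pytest

from streamoccu import CovariateBundle, DetectionHistory, CountHistory


@pytest.fixture
def empty_bundle():
    def make(site_ids):
        return CovariateBundle(
            pd.DataFrame(index=pd.Index(site_ids, name="site")))
    return make


@pytest.fixture
def small_bundle():
    rng = np.random.default_rng(5)
    ids = [f"s{i}" for i in range(6)]
    site = pd.DataFrame(
        {"forest": rng.standard_normal(6), "embed": rng.standard_normal(6)},
        index=pd.Index(ids, name="site"))
    obs = {"temp": pd.DataFrame(rng.standard_normal((6, 3)), index=site.index,
                                columns=["occ1", "occ2", "occ3"])}
    return CovariateBundle(site, obs)


@pytest.fixture
def small_history(small_bundle):
    rng = np.random.default_rng(9)
    y = (rng.random((6, 3)) < 0.6).astype(float)
    y[0] = 1.0  # keep at least one detected site
    return DetectionHistory(small_bundle.site_ids, y)


@pytest.fixture
def small_counts(small_bundle):
    rng = np.random.default_rng(13)
    c = rng.poisson(2.0, size=(6, 3)).astype(float)
    return CountHistory(small_bundle.site_ids, c)
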