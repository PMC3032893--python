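import numpy as np
import pytest

import tractica as tr


@pytest.fixture(scope="session")
def default_phantom():
    """The default study phantom: K=3 bundles, 24^3 grid, 6 subjects."""
    return tr.make_phantom(rng_seed=11)


@pytest.fixture(scope="session")
def default_stacks(default_phantom):
    return tr.sample_tractograms_direct(default_phantom, 5000, rng_seed=12)


@pytest.fixture(scope="session")
def default_group(default_stacks):
    return tr.GroupStack(default_stacks)


@pytest.fixture(scope="session")
def fitted_ica(default_group):
    return tr.GroupICA(n_components=3, random_state=0).fit(default_group)


@pytest.fixture(scope="session")
def noise_free_group():
    """Small noise-free phantom group (expectations, no Poisson draws)."""
    ph = tr.make_phantom(rng_seed=21, n_subjects=3, noise_floor=0.0)
    stacks = tr.sample_tractograms_direct(ph, 5000, rng_seed=22,
                                          noise="none")
    return ph, tr.GroupStack(stacks)


def match_components(truth_maps, est_maps):
    """Hungarian matching on |correlation|; returns (truth_idx, est_idx,
    matched |corr|)."""
    from scipy.optimize import linear_sum_assignment
    k, m = len(truth_maps), len(est_maps)
    corr = np.zeros((k, m))
    for i in range(k):
        for j in range(m):
            corr[i, j] = abs(np.corrcoef(truth_maps[i].ravel(),
                                         est_maps[j].ravel())[0, 1])
    ri, ci = linear_sum_assignment(-corr)
    return ri, ci, corr[ri, ci]
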