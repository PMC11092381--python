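import numpy as np
import pytest

import hemigrad as hg


@pytest.fixture(scope="session")
def parc20():
    return hg.make_parcellation(20, 7)


@pytest.fixture(scope="session")
def parc100():
    return hg.make_parcellation(100, 7)


@pytest.fixture(scope="session")
def small_cohort(parc100):
    """Eight-subject, 100-pair cohort with default planted effects."""
    truth = hg.default_ground_truth(parc100, seed=11)
    return hg.simulate_cohort(
        truth, parc100, n_mdd=4, n_hc=4, n_timepoints=160, seed=11
    )


@pytest.fixture(scope="session")
def small_result(small_cohort):
    """Analysis bundle for the small cohort (no prep: series are clean)."""
    cfg = hg.RunConfig(cohort_dir="", out_dir="", prep=False)
    return hg.analyze_cohort(small_cohort, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
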