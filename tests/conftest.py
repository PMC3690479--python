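import numpy as np
import pytest

from phosphodyn import synthetic_data as sd


@pytest.fixture(scope="session")
def cohort_2k():
    """Default-composition cohort of 2,000 sites with ground truth."""
    cfg = sd.GeneratorConfig(n_sites=2000, seed=42)
    records, ground_truth = sd.generate(cfg)
    return records, ground_truth, cfg


@pytest.fixture(scope="session")
def regulated_cohort():
    """1,500 all-regulated sites (for temporal/clustering tests)."""
    cfg = sd.GeneratorConfig(n_sites=1500, frac_regulated=1.0, seed=43)
    records, ground_truth = sd.generate(cfg)
    return records, ground_truth, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
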