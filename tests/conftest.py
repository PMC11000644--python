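import warnings

import numpy as np
import pandas as pd
import pytest

import metscate as mc

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Department-heterogeneous cohort, small enough for fast pipeline runs."""
    cfg = mc.study_cohort_config(surface="table3", n_unexposed=900,
                                 n_exposed=600, seed=7)
    return mc.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_result(small_cohort) -> mc.CateResult:
    return mc.estimate_pipeline(
        small_cohort, mc.PipelineConfig(featuresets=["original"], seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240405)
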