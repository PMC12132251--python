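import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from lungmeth import synthdata


@pytest.fixture(scope="session")
def small_cohort():
    """One seeded small cohort triple (beta, samples, truth)."""
    cfg = synthdata.CohortConfig(
        cohort_id="TEST", n_samples=80, n_cpgs=60, frac_causal=0.1, seed=11
    )
    return synthdata.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_annotation():
    return synthdata.generate_annotation(60, seed=11)


@pytest.fixture()
def toy_beta():
    """Tiny hand-made beta matrix with a missing cell."""
    return pd.DataFrame(
        {
            "s1": [0.2, 0.5, 0.9, 0.4],
            "s2": [0.25, 0.5, 0.85, np.nan],
            "s3": [0.22, 0.5, 0.88, 0.41],
        },
        index=pd.Index(["cg1", "cg2", "cg3", "cg4"], name="cpg_id"),
    )
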