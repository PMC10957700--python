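import numpy as np
import pandas as pd
import pytest

from ctp_cea import ModelParameters, synthesize_cohort
from ctp_cea.cohort import Cohort


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def cohort701():
    return synthesize_cohort(n=701, seed=7)


@pytest.fixture(scope="session")
def cohort_small():
    return synthesize_cohort(n=120, seed=11)


def make_cohort(
    mrs, occlusion="M1", age=72, sex="male", ivt=True, latent_u=None
) -> Cohort:
    """Hand-built cohort with explicit 90-day states for targeted tests."""
    mrs = np.asarray(mrs, dtype=int)
    n = mrs.size
    rng = np.random.default_rng(1234)
    frame = pd.DataFrame(
        {
            "id": np.arange(n),
            "age": np.full(n, age),
            "sex": np.full(n, sex, dtype=object),
            "occlusion": np.full(n, occlusion, dtype=object),
            "mrs90_treated": mrs,
            "ivt": np.full(n, ivt, dtype=bool),
            "latent_u": rng.random(n).clip(1e-9, 1 - 1e-9)
            if latent_u is None
            else np.full(n, latent_u, dtype=float),
        }
    )
    return Cohort(frame, provenance="synthetic", seed=0)
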