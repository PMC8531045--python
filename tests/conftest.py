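import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from deliriscore.cohort import (
    BINARY,
    CONTINUOUS,
    OUTCOME_NAME,
    Cohort,
    VariableSpec,
)
from deliriscore.simulate import BinaryCovariate, CohortSpec

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def make_cohort(outcome, label="test", **columns) -> Cohort:
    """Build a small in-memory cohort; kind inferred from values."""
    outcome = np.asarray(outcome, dtype=float)
    data = pd.DataFrame({"id": np.arange(len(outcome)), OUTCOME_NAME: outcome})
    registry = [VariableSpec(OUTCOME_NAME, BINARY, role="outcome")]
    for name, vals in columns.items():
        vals = np.asarray(vals, dtype=float)
        kind = BINARY if np.all(np.isin(vals[~np.isnan(vals)], (0, 1))) else CONTINUOUS
        registry.append(VariableSpec(name, kind, role="candidate"))
        data[name] = vals
    return Cohort(data, registry, label=label)


@pytest.fixture
def make_cohort_fixture():
    return make_cohort


def planted_score_spec(n: int = 5000) -> CohortSpec:
    """Generating model with four strong score components (published
    conditional ORs) plus three null candidates; used for recovery checks."""
    covs = [
        BinaryCovariate("age_ge75", 0.65),
        BinaryCovariate("dementia", 0.25),
        BinaryCovariate("hearing_impairment", 0.20),
        BinaryCovariate("psychotropics", 0.30),
        BinaryCovariate("noise_a", 0.30),
        BinaryCovariate("noise_b", 0.20),
        BinaryCovariate("noise_c", 0.15),
    ]
    effects = {
        "age_ge75": math.log(9.22),
        "dementia": math.log(18.33),
        "hearing_impairment": math.log(8.07),
        "psychotropics": math.log(5.55),
        "noise_a": 0.0,
        "noise_b": 0.0,
        "noise_c": 0.0,
    }
    return CohortSpec(n=n, covariates=covs, effects=effects, target_prevalence=0.161)


PLANTED_COMPONENTS = frozenset(
    {"age_ge75", "dementia", "hearing_impairment", "psychotropics"}
)
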