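"""Shared fixtures: cohorts and expression matrices reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from mirblood.preprocess import ExpressionMatrix, normalize_cohort
from mirblood.synthetic import SyntheticSpec, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort at the default study conditions."""
    return generate_cohort(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def normalized_default(default_cohort):
    expr, params = normalize_cohort(default_cohort)
    return expr, params


@pytest.fixture(scope="session")
def null_cohort():
    """Full-size cohort with no planted effects."""
    return generate_cohort(SyntheticSpec(n_differential=0, seed=13))


def make_expression(x: np.ndarray, labels: list[str] | np.ndarray) -> ExpressionMatrix:
    """Wrap a features-x-samples array as an ExpressionMatrix with labels."""
    cols = [f"s{i:03d}" for i in range(x.shape[1])]
    values = pd.DataFrame(x, index=[f"f{k:04d}" for k in range(x.shape[0])], columns=cols)
    return ExpressionMatrix(
        values=values, labels=pd.Series(np.asarray(labels), index=cols, name="group")
    )
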