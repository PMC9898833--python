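import numpy as np
import pandas as pd
import pytest

from emrprep.cohort import Cohort, make_meta
from emrprep.synthetic import CohortSpec, generate_cohort, study_spec


@pytest.fixture(scope="session")
def study_cohort():
    """Small study-shaped cohort: 5% positives, missingness, separating dx."""
    return generate_cohort(study_spec(seed=11, n_pos=60, n_neg=1140))


@pytest.fixture(scope="session")
def complete_cohort():
    """Same shape, no missingness (for stages that need complete matrices)."""
    return generate_cohort(study_spec(seed=11, n_pos=60, n_neg=1140,
                                      missing=False))


def toy_cohort(columns: dict, kinds: dict, outcome=None, ref_ranges=None):
    """Hand-built cohort from explicit columns."""
    data = pd.DataFrame({k: pd.array(v, dtype=float) for k, v in columns.items()})
    n = len(data)
    if outcome is None:
        outcome = [0, 1] * (n // 2) + [0] * (n % 2)
    meta = make_meta(list(columns), [kinds[c] for c in columns],
                     ref_ranges=ref_ranges)
    return Cohort(data=data, outcome=pd.Series(outcome), meta=meta)
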