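import numpy as np
import pandas as pd
import pytest

from metabosig import (CohortTable, classify_metabolite_name, simulate_cohort,
                       two_group_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel():
    return [classify_metabolite_name(n)
            for n in ("lysoPCaC16:0", "lysoPCaC28:1", "PCaaC32:3", "PCaaC38:0",
                      "PCaeC38:0", "PCaeC40:6")]


@pytest.fixture
def tiny_cohort(small_panel):
    """60-participant two-group cohort with one discriminative metabolite."""
    return simulate_cohort(two_group_config(
        30, 30, small_panel, seed=7, effects={"PCaaC32:3": 0.8},
        rho_within_class=0.3))


def make_cohort_frame(n=6, metabolites=("PCaaC32:3", "PCaeC38:0"), seed=0):
    """Hand-rolled cohort DataFrame for IO tests."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "subject_id": [f"P{i}" for i in range(n)],
        "group": ["OA", "HV"] * (n // 2),
        "age": rng.uniform(35, 75, n).round(1),
        "sex": ["male", "female"] * (n // 2),
        "bmi": rng.uniform(20, 40, n).round(1),
        "batch": ["B1"] * n,
    })
    for m in metabolites:
        df[m] = rng.uniform(0.1, 50, n).round(3)
    return df


@pytest.fixture
def cohort_frame():
    return make_cohort_frame()


@pytest.fixture
def cohort(cohort_frame):
    return CohortTable(cohort_frame.copy())
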