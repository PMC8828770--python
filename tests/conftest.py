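"""Shared fixtures: small synthetic cohorts and on-disk tabular fixtures.

Expensive simulated cohorts are session-scoped; every generator call is
explicitly seeded so the suite is deterministic.
"""

import numpy as np
import pandas as pd
import pytest

import appliscore as ap
from appliscore.io_cohort import ClinicalTable, Cohort, ExpressionMatrix


@pytest.fixture(scope="session")
def centroids():
    return ap.simulate_centroids(n_genes=50, seed=11)


@pytest.fixture(scope="session")
def planted_sim():
    """Classification cohort with the score informative only in ER+ patients."""
    return ap.simulate_classification_cohort(
        ap.SimulationConfig(n=600, effect_beta=2.0, applicable_fraction=0.5, seed=3)
    )


@pytest.fixture(scope="session")
def uniform_sim():
    """Classification cohort where the biomarker applies to everyone."""
    return ap.simulate_classification_cohort(
        ap.SimulationConfig(n=400, effect_beta=2.0, applicable_fraction=1.0, seed=8)
    )


@pytest.fixture(scope="session")
def survival_sim():
    """Survival cohort, biomarker informative in every patient (beta=1)."""
    return ap.simulate_survival_cohort(
        ap.SimulationConfig(n=400, effect_beta=1.0, applicable_fraction=1.0, seed=6)
    )


@pytest.fixture(scope="session")
def cpm_spec():
    return ap.PredictorSpec("score", ("age", "er_status", "stage"))


@pytest.fixture(scope="session")
def ppm_spec():
    return ap.PredictorSpec(None, ("age", "er_status", "stage", "subtype"))


@pytest.fixture
def tiny_expression():
    """3 genes x 2 samples, hand-enumerable."""
    df = pd.DataFrame(
        {"s1": [4.0, 6.0, 1.5], "s2": [6.0, 8.0, 2.5]},
        index=["p1", "p2", "p3"],
    )
    return ExpressionMatrix(df)


def make_cohort(clin: pd.DataFrame, name: str = "test") -> Cohort:
    return Cohort(clinical=ClinicalTable(clin), name=name)


@pytest.fixture
def separable_cohort():
    """Response fully determined by the sign of the score."""
    rng = np.random.default_rng(42)
    n = 200
    score = rng.normal(0, 1, n)
    clin = pd.DataFrame(
        {
            "age": rng.normal(55, 10, n),
            "er_status": rng.choice(["positive", "negative"], n),
            "stage": rng.choice(["1", "2", "3"], n),
            "response": np.where(score > 0, "pCR", "RD"),
        },
        index=[f"T{i:04d}" for i in range(n)],
    )
    scores = pd.Series(score, index=clin.index, name="score")
    return make_cohort(clin), scores
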