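"""Seeded synthetic cohorts with planted biomarker applicability.

The generators encode the framework's core premise: a biomarker score that
is informative only within a covariate-defined stratum of patients. The
applicable stratum is keyed to ER status (ER-positive = applicable), the
score is standard normal, and the outcome model is

* classification — ``logit P(pCR) = intercept + beta * score`` inside the
  stratum and ``intercept`` alone outside; the intercept is calibrated per
  stratum so that each stratum (hence the cohort) hits the target pCR
  prevalence (0.25 by default, imbalanced as in real neoadjuvant cohorts).
  Equal prevalence across strata keeps score informativeness the *only*
  planted difference between strata.
* survival — exponential event times with hazard
  ``baseline_hazard * exp(beta * score)`` inside the stratum and the
  baseline hazard outside, independently exponentially censored.

All generators are pure functions of (config, seed): reruns are
byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io_cohort import (
    CentroidProfiles,
    ClinicalTable,
    Cohort,
    ExpressionMatrix,
    SUBTYPE_ORDER,
)

logger = logging.getLogger("appliscore")

STAGE_PROBS = {"1": 0.3, "2": 0.5, "3": 0.2}
SUBTYPE_PROBS = {"Basal": 0.2, "Her2": 0.15, "LumA": 0.35, "LumB": 0.2, "Normal": 0.1}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohorts.

    ``effect_beta`` is the log-odds (classification) or log-hazard
    (survival) per unit score inside the applicable stratum;
    ``applicable_fraction`` the probability of being ER-positive (the
    applicable stratum); ``prevalence`` the target marginal pCR rate;
    ``baseline_hazard``/``censoring_rate`` are exponential rates in inverse
    time units (defaults give roughly 30% censoring).
    """

    n: int = 1000
    applicable_fraction: float = 0.5
    effect_beta: float = 2.0
    noise_sd: float = 0.5
    prevalence: float = 0.25
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be positive")
        if not (0 < self.applicable_fraction <= 1):
            raise ValueError("applicable_fraction must be in (0, 1]")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must be in (0, 1)")
        for name in ("noise_sd", "baseline_hazard", "censoring_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class SimulatedCohort(NamedTuple):
    cohort: Cohort
    scores: pd.Series
    applicable: pd.Series  # bool per sample: true stratum membership


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _calibrate_intercept(latent: np.ndarray, target: float) -> float:
    """Bisection for `a` such that mean(sigmoid(a + latent)) == target."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = (lo + hi) / 2
        if _sigmoid(mid + latent).mean() < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _covariates(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n
    ids = [f"S{i:05d}" for i in range(1, n + 1)]
    applicable = rng.random(n) < config.applicable_fraction
    return pd.DataFrame(
        {
            "age": np.round(rng.normal(55.0, 10.0, n), 2),
            "er_status": np.where(applicable, "positive", "negative"),
            "stage": rng.choice(list(STAGE_PROBS), size=n, p=list(STAGE_PROBS.values())),
            "subtype": rng.choice(list(SUBTYPE_PROBS), size=n, p=list(SUBTYPE_PROBS.values())),
            "_applicable": applicable,
        },
        index=pd.Index(ids, name="sample_id"),
    )


def simulate_classification_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Binary-response cohort with the score informative only in the
    ER-positive stratum; marginal pCR prevalence hits the configured target.
    """
    rng = np.random.default_rng(config.seed)
    cov = _covariates(config, rng)
    applicable = cov.pop("_applicable")
    score = rng.normal(0.0, 1.0, config.n)
    latent = np.where(applicable, config.effect_beta * score, 0.0)
    prob = np.empty(config.n)
    for stratum in (True, False):
        mask = applicable.to_numpy() == stratum
        if mask.any():
            a = _calibrate_intercept(latent[mask], config.prevalence)
            prob[mask] = _sigmoid(a + latent[mask])
    response = np.where(rng.random(config.n) < prob, "pCR", "RD")
    clin = cov.assign(response=response)
    cohort = Cohort(clinical=ClinicalTable(clin), name="simulated-classification")
    scores = pd.Series(score, index=clin.index, name="biomarker_score")
    logger.info(
        "simulate_classification_cohort: n=%d, pCR prevalence %.3f, applicable %.3f",
        config.n, float((response == "pCR").mean()), float(applicable.mean()),
    )
    return SimulatedCohort(cohort, scores, applicable.rename("applicable"))


def simulate_survival_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Right-censored survival cohort: exponential event times with hazard
    ``baseline_hazard * exp(beta * score)`` inside the stratum, independent
    exponential censoring; realised censoring fraction is logged."""
    rng = np.random.default_rng(config.seed)
    cov = _covariates(config, rng)
    applicable = cov.pop("_applicable")
    score = rng.normal(0.0, 1.0, config.n)
    hazard = config.baseline_hazard * np.exp(
        np.where(applicable, config.effect_beta * score, 0.0)
    )
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.exponential(1.0 / config.censoring_rate, config.n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    clin = cov.assign(time=time, event=event)
    cohort = Cohort(clinical=ClinicalTable(clin), name="simulated-survival")
    scores = pd.Series(score, index=clin.index, name="biomarker_score")
    logger.info(
        "simulate_survival_cohort: n=%d, censoring fraction %.3f",
        config.n, float(1 - event.mean()),
    )
    return SimulatedCohort(cohort, scores, applicable.rename("applicable"))


def simulate_centroids(n_genes: int = 50, n_subtypes: int = 5, seed: int = 0) -> CentroidProfiles:
    """Synthetic centroid profiles (log2-intensity scale) for subtyping
    fixtures: independent N(8, 1) expression per gene and subtype."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    names = list(SUBTYPE_ORDER[:n_subtypes])
    values = pd.DataFrame(rng.normal(8.0, 1.0, (n_genes, n_subtypes)), index=genes, columns=names)
    return CentroidProfiles(values)


def make_subtype_samples(
    centroids: CentroidProfiles,
    per_subtype: int,
    noise_sd: float,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Expression fixture for subtyping: each sample is one centroid column
    plus iid N(0, noise_sd) noise; the truth Series records the generating
    subtype."""
    if per_subtype < 1:
        raise ValueError("per_subtype must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    cols, truth = {}, {}
    for name in centroids.subtype_names:
        base = centroids.values[name].to_numpy()
        for i in range(1, per_subtype + 1):
            sid = f"{name}_{i:03d}"
            cols[sid] = base + rng.normal(0.0, noise_sd, len(base))
            truth[sid] = name
    matrix = ExpressionMatrix(pd.DataFrame(cols, index=centroids.gene_ids))
    return matrix, pd.Series(truth, name="true_subtype")
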