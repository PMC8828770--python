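"""Predictability labels, the predictability prediction model (PPM), and C-scores.

The PPM is a meta-classifier: given a CPM's track record on a benchmark
cohort, patients are labelled *positive* (correctly/well predicted) or
*negative* (incorrectly/poorly predicted), and a classifier over clinical
features learns to separate the two groups. Its output probability for the
positive class is the confidence score (C-score): the estimated
applicability of the CPM — and hence of the underlying biomarker — to a
patient.

Labelling rules:

* classification — a patient is predicted pCR iff P-score > 0.5 (strict);
  positive iff the prediction matches the observed response.
* survival — restrict to patients whose number of effective comparisons is
  at least ``floor(0.2 * cohort size)``; positive iff the sample-specific
  concordance strictly exceeds the overall concordance.

Label groups are balanced by down-sampling the larger group before fitting,
mirroring the CPM training protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .concordance import ConcordanceDecomposition, effective_fraction_filter
from .cpm import (
    DEFAULT_N_TREES,
    PredictorSpec,
    PScore,
    _fit_balanced_classifier,
    design_matrix,
)
from .io_cohort import Cohort

logger = logging.getLogger("appliscore")

#: C-scores: float Series in [0, 1] indexed by sample id; NaN = missing
#: predictors.
CScore = pd.Series

POSITIVE, NEGATIVE = 1, 0  # correctly/well predicted vs incorrectly/poorly


@dataclass
class PredictabilityLabels:
    """Per-sample predictability labels feeding PPM training.

    ``labels`` maps retained sample ids to 1 (correctly/well predicted) or
    0 (incorrectly/poorly predicted). ``provenance`` records whether the
    underlying P-scores were in-sample or out-of-fold; ``filter_mask`` is
    the survival-branch effective-fraction mask (None for classification).
    """

    labels: pd.Series
    source: str  # "classification" | "survival"
    provenance: str  # "in_sample" | "out_of_fold"
    filter_mask: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.labels.dropna().isin([0, 1]).all():
            raise ValueError("labels must be binary (1 positive, 0 negative)")
        if self.filter_mask is not None:
            retained = set(self.filter_mask.index[self.filter_mask])
            if not set(self.labels.index) <= retained:
                raise ValueError("labelled samples must pass the filter mask")


def label_classification_predictability(
    pscores: PScore,
    truth: pd.Series,
    threshold: float = 0.5,
    provenance: str = "out_of_fold",
) -> PredictabilityLabels:
    """Correct/incorrect labels from classification P-scores.

    A patient is predicted pCR iff ``p_score > threshold`` (strict, so a
    P-score of exactly 0.5 predicts RD); the label is positive iff the
    prediction matches the observed response. Samples with missing truth or
    P-score are excluded (logged).
    """
    common = pscores.index.intersection(truth.index)
    p = pscores.loc[common]
    t = truth.loc[common]
    ok = p.notna() & t.notna()
    n_excluded = len(pscores.index.union(truth.index)) - int(ok.sum())
    if n_excluded:
        logger.info(
            "label_classification_predictability: excluded %d samples "
            "(missing P-score or outcome)", n_excluded,
        )
    predicted_pcr = p.loc[ok] > threshold
    actual_pcr = t.loc[ok] == "pCR"
    labels = (predicted_pcr == actual_pcr).astype(int)
    labels.name = "predictability"
    return PredictabilityLabels(labels=labels, source="classification", provenance=provenance)


def label_survival_predictability(
    decomp: ConcordanceDecomposition,
    cohort_size: int | None = None,
    fraction: float = 0.2,
    provenance: str = "in_sample",
) -> PredictabilityLabels:
    """Well/poor labels from the concordance decomposition.

    Samples failing the effective-fraction filter (or with undefined
    sample-specific concordance) are excluded; among the retained, positive
    iff ``c_sample`` strictly exceeds the overall concordance (exact
    equality is negative).
    """
    mask = effective_fraction_filter(decomp, cohort_size=cohort_size, fraction=fraction)
    retained = mask & decomp.c_sample.notna()
    if not retained.any():
        raise ValueError("every sample was removed by the effective-fraction filter")
    labels = (decomp.c_sample.loc[retained] > decomp.overall).astype(int)
    labels.name = "predictability"
    logger.info(
        "label_survival_predictability: %d well / %d poor (cutoff %.4f)",
        int(labels.sum()), int((1 - labels).sum()), decomp.overall,
    )
    return PredictabilityLabels(
        labels=labels, source="survival", provenance=provenance, filter_mask=retained
    )


@dataclass
class PPMFit:
    """A fitted PPM with its predictor contract and balancing log."""

    model: RandomForestClassifier
    predictors: PredictorSpec
    feature_names: tuple[str, ...]
    source: str = "classification"
    provenance: str = "out_of_fold"
    train_log: dict = field(default_factory=dict)


def train_ppm(
    cohort: Cohort,
    labels: PredictabilityLabels,
    predictors: PredictorSpec,
    n_trees: int = DEFAULT_N_TREES,
    balance: bool = True,
    seed: int = 0,
    scores: pd.Series | None = None,
) -> PPMFit:
    """Train the predictability classifier on balanced label groups.

    ``predictors`` normally lists clinical columns only (``score_column``
    None); group sizes before/after balancing go to the train log. When the
    PPM shares predictors with its CPM the overlap is kept and logged.
    """
    X, complete = design_matrix(cohort, scores, predictors)
    y = labels.labels.reindex(X.index)
    usable = complete & y.notna()
    n_excluded = int((~usable & y.notna()).sum())
    if n_excluded:
        logger.info("train_ppm: excluded %d labelled samples with missing predictors", n_excluded)
    present = y.loc[usable].value_counts().to_dict()
    if len(present) < 2:
        raise ValueError(f"both label classes required to train the PPM; got {present}")
    model, log = _fit_balanced_classifier(
        X.loc[usable], y.loc[usable].astype(int), n_trees, balance, seed, positive=POSITIVE
    )
    log["n_excluded"] = n_excluded
    return PPMFit(
        model=model,
        predictors=predictors,
        feature_names=tuple(X.columns),
        source=labels.source,
        provenance=labels.provenance,
        train_log=log,
    )


def predict_cscore(
    fit: PPMFit, cohort: Cohort, scores: pd.Series | None = None
) -> CScore:
    """C-score = predicted probability that the CPM's call is correct;
    NaN where predictors are missing (logged)."""
    X, complete = design_matrix(cohort, scores, fit.predictors)
    X = X[list(fit.feature_names)]
    out = pd.Series(np.nan, index=X.index, name="c_score")
    if complete.any():
        proba = fit.model.predict_proba(X.loc[complete].to_numpy())
        pos = list(fit.model.classes_).index(POSITIVE)
        out.loc[complete] = proba[:, pos]
    n_missing = int((~complete).sum())
    if n_missing:
        logger.info("predict_cscore: %d samples got missing C-scores", n_missing)
    return out
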