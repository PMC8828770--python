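"""Repeated cross-validated AUC, drop-predictor importance, and
C-score-sorted accuracy curves.

Cross-validation follows the balanced-training protocol: within each
repeat, samples are split into stratified folds; each fold is predicted by
a model trained (with majority down-sampling) on the other folds; the
pooled out-of-fold predictions yield one ROC/AUC per repeat and the mean
over repeats is reported.

The accuracy curve is the framework's selective-prediction readout:
patients sorted by decreasing C-score, the running mean of a per-patient
outcome metric (correctness indicator or sample-specific concordance) over
the top N, optionally smoothed with a centred sliding window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .cpm import DEFAULT_N_TREES, PredictorSpec, _child_seed, _fit_balanced_classifier, design_matrix
from .io_cohort import Cohort
from .ppm import CScore

logger = logging.getLogger("appliscore")


@dataclass
class CVResult:
    """Repeated stratified k-fold AUC estimate."""

    auc_per_repeat: tuple[float, ...]
    folds: int
    repeats: int
    seed: int

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc_per_repeat))


def _binary_outcome(cohort: Cohort, outcome: pd.Series | None, outcome_column: str) -> pd.Series:
    if outcome is None:
        outcome = cohort.clinical.data[outcome_column]
    if outcome.dtype == object:
        if set(outcome.dropna()) - {"pCR", "RD"}:
            raise ValueError("string outcomes must be pCR/RD")
        return outcome.map({"pCR": 1, "RD": 0})
    return outcome.astype(float)


def cross_validated_auc(
    cohort: Cohort,
    scores: pd.Series | None,
    predictors: PredictorSpec,
    task: str = "classify",
    outcome: pd.Series | None = None,
    outcome_column: str = "response",
    folds: int = 10,
    repeats: int = 10,
    n_trees: int = DEFAULT_N_TREES,
    balance: bool = True,
    seed: int = 0,
) -> CVResult:
    """Mean AUC over repeated stratified k-fold cross-validation.

    ``outcome`` overrides the cohort's outcome column — used to estimate
    PPM accuracy by passing predictability labels. Down-sampling is applied
    inside each training fold; fold assignment depends only on the seed and
    a canonical sample sort, not on input order.
    """
    if task != "classify":
        raise ValueError("cross_validated_auc supports the classification task")
    X, complete = design_matrix(cohort, scores, predictors)
    y = _binary_outcome(cohort, outcome, outcome_column).reindex(X.index)
    usable = complete & y.notna()
    order = np.argsort(X.index[usable])  # canonical sort: seed decides folds
    Xu = X.loc[usable].iloc[order]
    yu = y.loc[usable].iloc[order].astype(int)
    if yu.value_counts().min() < folds:
        raise ValueError("need at least `folds` samples in each outcome class")

    aucs = []
    for r in range(repeats):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=_child_seed(seed, 100 + r)
        )
        oof = pd.Series(np.nan, index=Xu.index)
        for k, (tr, te) in enumerate(skf.split(Xu.to_numpy(), yu.to_numpy())):
            model, _ = _fit_balanced_classifier(
                Xu.iloc[tr], yu.iloc[tr], n_trees, balance,
                _child_seed(seed, 1000 + r * folds + k), positive=1,
            )
            pos = list(model.classes_).index(1)
            oof.iloc[te] = model.predict_proba(Xu.iloc[te].to_numpy())[:, pos]
        aucs.append(float(roc_auc_score(yu.to_numpy(), oof.to_numpy())))
    return CVResult(auc_per_repeat=tuple(aucs), folds=folds, repeats=repeats, seed=seed)


def drop_column_importance(
    cohort: Cohort,
    scores: pd.Series | None,
    predictors: PredictorSpec,
    metric: str = "auc",
    seed: int = 0,
    **cv_kwargs,
) -> dict[str, float]:
    """Relative importance of each predictor as the cross-validated AUC drop
    when it is excluded and the model refit (same seed throughout).

    Known limitation: duplicated/redundant predictors each show near-zero
    drop importance.
    """
    if metric != "auc":
        raise ValueError("only the AUC metric is supported")
    cols = predictors.all_columns()
    if len(cols) < 2:
        raise ValueError("drop-column importance needs at least 2 predictors")
    full = cross_validated_auc(cohort, scores, predictors, seed=seed, **cv_kwargs).mean_auc
    table = {}
    for col in cols:
        reduced = predictors.drop(col)
        auc = cross_validated_auc(cohort, scores, reduced, seed=seed, **cv_kwargs).mean_auc
        table[col] = full - auc
    return table


@dataclass
class SortedAccuracyCurve:
    """Accuracy/concordance as a function of C-score rank.

    ``data`` columns: rank (1-based), sample_id, c_score, metric,
    cumulative (mean metric over the top-N patients), smoothed (centred
    moving average of the cumulative series, window truncated at edges).
    """

    data: pd.DataFrame
    window: int

    @property
    def cumulative(self) -> np.ndarray:
        return self.data["cumulative"].to_numpy()

    @property
    def smoothed(self) -> np.ndarray:
        return self.data["smoothed"].to_numpy()

    def decile_gap(self) -> float:
        """Mean cumulative accuracy over the top decile of ranks minus the
        mean over the bottom decile — the curve's headline contrast."""
        n = len(self.data)
        k = max(1, n // 10)
        cum = self.cumulative
        return float(cum[:k].mean() - cum[-k:].mean())


def sorted_accuracy_curve(
    cscores: CScore,
    metric: pd.Series,
    window: int = 20,
) -> SortedAccuracyCurve:
    """Sort patients by decreasing C-score and accumulate the outcome metric.

    ``metric`` is a per-sample real — a 0/1 correctness indicator
    (classification) or the sample-specific concordance (survival). Samples
    with an undefined metric or C-score are excluded (logged); C-score ties
    are broken by sample id (logged).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    common = cscores.index.intersection(metric.index)
    df = pd.DataFrame({"c_score": cscores.loc[common], "metric": metric.loc[common]})
    n_dropped = int(df.isna().any(axis=1).sum())
    if n_dropped:
        logger.info("sorted_accuracy_curve: excluded %d samples with undefined values", n_dropped)
    df = df.dropna()
    if df.empty:
        raise ValueError("no samples with both a C-score and a defined metric")
    if df["c_score"].duplicated().any():
        logger.info("sorted_accuracy_curve: C-score ties broken by sample id order")
    # decreasing C-score, ties broken by ascending sample id
    df = df.iloc[np.lexsort((df.index.to_numpy(), -df["c_score"].to_numpy()))]
    n = len(df)
    cumulative = df["metric"].to_numpy(dtype=float).cumsum() / np.arange(1, n + 1)
    smoothed = (
        pd.Series(cumulative).rolling(window=window, center=True, min_periods=1).mean().to_numpy()
    )
    out = pd.DataFrame(
        {
            "rank": np.arange(1, n + 1),
            "sample_id": df.index,
            "c_score": df["c_score"].to_numpy(),
            "metric": df["metric"].to_numpy(),
            "cumulative": cumulative,
            "smoothed": smoothed,
        }
    )
    return SortedAccuracyCurve(data=out, window=window)
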