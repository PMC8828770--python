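"""Clinical outcome prediction models (CPMs) producing per-patient P-scores.

Two branches:

* classification — a probabilistic classifier (random-forest backbone by
  default) for binary response (pCR vs RD); the P-score is the predicted
  pCR probability. Class imbalance is handled by down-sampling the majority
  class once before fitting; discarded samples are still scored.
* survival — a univariate Cox proportional-hazards model (Efron tie
  handling) or a random survival forest; the P-score is a relative-risk
  ranking score (higher = higher risk, i.e. shorter predicted survival).

Samples missing any predictor are excluded from fitting and receive a
missing P-score at prediction time (listwise exclusion, logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sksurv.ensemble import RandomSurvivalForest
from sksurv.util import Surv

from .io_cohort import CLINICAL_LEVELS, Cohort
from .signatures import SignatureScores

logger = logging.getLogger("appliscore")

#: P-scores: float Series indexed by sample id; NaN = missing predictors.
PScore = pd.Series

#: Default tree count for the random-forest backbone (classification CPM and
#: PPM alike); tests and desk-scale runs pass a smaller count explicitly.
DEFAULT_N_TREES = 10_000

#: Default tree count for the random survival forest.
DEFAULT_RSF_TREES = 500


def _child_seed(seed: int, k: int) -> int:
    """Deterministic derived seed, kept below 2**31."""
    return (int(seed) * 69069 + k * 7919 + 1) % (2**31 - 1)


# ---------------------------------------------------------------------------
# Predictor specification and design matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PredictorSpec:
    """Which columns feed a model and how categoricals are encoded.

    ``score_column`` names the signature-score predictor (None for models
    without one, e.g. a PPM on clinical features only). ``encoding`` maps a
    categorical column to ``"onehot"`` (default; reference = first declared
    level, dropped) or ``"ordinal"`` (integer codes in declared level order).
    """

    score_column: str | None
    clinical_columns: tuple[str, ...]
    encoding: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = list(self.all_columns())
        if len(cols) != len(set(cols)):
            raise ValueError("duplicate predictor columns")
        for col, enc in self.encoding.items():
            if enc not in ("onehot", "ordinal"):
                raise ValueError(f"unknown encoding {enc!r} for column {col!r}")

    def all_columns(self) -> tuple[str, ...]:
        cols = () if self.score_column is None else (self.score_column,)
        return cols + tuple(self.clinical_columns)

    def drop(self, column: str) -> "PredictorSpec":
        if column == self.score_column:
            return PredictorSpec(None, self.clinical_columns, self.encoding)
        if column in self.clinical_columns:
            return PredictorSpec(
                self.score_column,
                tuple(c for c in self.clinical_columns if c != column),
                self.encoding,
            )
        raise ValueError(f"{column!r} is not a predictor")


def design_matrix(
    cohort: Cohort,
    scores: SignatureScores | None,
    predictors: PredictorSpec,
) -> tuple[pd.DataFrame, pd.Series]:
    """Numeric design matrix plus a per-sample completeness mask.

    Categorical levels come from the declared dictionary so that encoded
    columns are identical between training and application cohorts.
    """
    clin = cohort.clinical.data
    raw = {}
    if predictors.score_column is not None:
        if scores is None:
            raise ValueError(f"predictor {predictors.score_column!r} needs signature scores")
        raw[predictors.score_column] = scores.reindex(clin.index).astype(float)
    for col in predictors.clinical_columns:
        if col not in clin.columns:
            raise ValueError(f"predictor column {col!r} absent from cohort {cohort.name!r}")
        raw[col] = clin[col]
    raw_df = pd.DataFrame(raw, index=clin.index)
    complete = raw_df.notna().all(axis=1)

    pieces: list[pd.DataFrame] = []
    for col in raw_df.columns:
        series = raw_df[col]
        levels = CLINICAL_LEVELS.get(col)
        if levels is None and series.dtype == object:
            levels = tuple(sorted(series.dropna().unique()))
            logger.warning(
                "design_matrix: column %r has no declared levels; using observed %s",
                col, levels,
            )
        if levels is None:
            pieces.append(series.astype(float).to_frame(col))
        elif predictors.encoding.get(col, "onehot") == "ordinal":
            codes = pd.Categorical(series, categories=levels).codes.astype(float)
            codes[codes < 0] = np.nan
            pieces.append(pd.DataFrame({col: codes}, index=raw_df.index))
        else:  # one-hot, reference = first declared level
            cat = pd.Categorical(series, categories=levels)
            dummies = pd.get_dummies(cat, prefix=col, dtype=float)
            dummies.index = raw_df.index
            dummies = dummies.iloc[:, 1:]
            dummies.loc[series.isna(), :] = np.nan
            pieces.append(dummies)
    X = pd.concat(pieces, axis=1)
    return X, complete


# ---------------------------------------------------------------------------
# Class balancing
# ---------------------------------------------------------------------------


def downsample_majority(labels: pd.Series, seed: int) -> pd.Index:
    """Balanced subset of sample ids: all minority samples plus a uniformly
    random, seed-reproducible majority subset of equal size.

    The returned index preserves the input order. Raises if a class is
    absent.
    """
    labels = labels.dropna()
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError(f"both classes required for down-sampling; got {dict(counts)}")
    if len(counts) != 2:
        raise ValueError(f"binary labels required; got levels {list(counts.index)}")
    minority = counts.idxmin()
    majority = counts.idxmax()
    if counts[minority] == counts[majority]:
        return labels.index
    rng = np.random.default_rng(seed)
    majority_ids = labels.index[labels == majority]
    keep_majority = set(
        rng.choice(np.asarray(majority_ids, dtype=object), size=int(counts[minority]), replace=False)
    )
    keep = [
        s for s, lab in labels.items()
        if lab == minority or s in keep_majority
    ]
    return pd.Index(keep)


# ---------------------------------------------------------------------------
# Classification CPM
# ---------------------------------------------------------------------------


@dataclass
class ClassificationCPMFit:
    """A fitted classification CPM with its predictor contract and train log."""

    model: RandomForestClassifier
    predictors: PredictorSpec
    feature_names: tuple[str, ...]
    classes: tuple[str, str] = ("pCR", "RD")
    train_log: dict = field(default_factory=dict)


def _fit_balanced_classifier(
    X: pd.DataFrame,
    y: pd.Series,
    n_trees: int,
    balance: bool,
    seed: int,
    positive: str,
) -> tuple[RandomForestClassifier, dict]:
    """Shared fitting core for the classification CPM and the PPM."""
    counts_before = y.value_counts().to_dict()
    if balance:
        idx = downsample_majority(y, seed=_child_seed(seed, 0))
        X, y = X.loc[idx], y.loc[idx]
        counts = y.value_counts()
        assert counts.nunique() == 1, "balanced training requires equal class counts"
    counts_after = y.value_counts().to_dict()
    if min(counts_after.values(), default=0) < 2 or len(counts_after) < 2:
        raise ValueError(f"need >=2 samples per class to fit; got {counts_after}")
    model = RandomForestClassifier(
        n_estimators=int(n_trees), random_state=_child_seed(seed, 1), n_jobs=1
    )
    model.fit(X.to_numpy(), y.to_numpy())
    log = {
        "class_counts_before": counts_before,
        "class_counts_after": counts_after,
        "seed": seed,
        "positive_class": positive,
        "n_trees": int(n_trees),
    }
    logger.info("balanced fit: %s -> %s (seed %d)", counts_before, counts_after, seed)
    return model, log


def fit_classification_cpm(
    cohort: Cohort,
    scores: SignatureScores | None,
    predictors: PredictorSpec,
    n_trees: int = DEFAULT_N_TREES,
    balance: bool = True,
    seed: int = 0,
    outcome_column: str = "response",
) -> ClassificationCPMFit:
    """Fit the binary-response CPM (pCR vs RD) on complete-case samples.

    With ``balance=True`` (default) the majority class is down-sampled to
    the minority size before fitting; discarded samples are still scored at
    prediction time.
    """
    X, complete = design_matrix(cohort, scores, predictors)
    y = cohort.clinical.data[outcome_column]
    usable = complete & y.notna()
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info(
            "fit_classification_cpm: excluded %d samples with missing predictors/outcome",
            n_excluded,
        )
    model, log = _fit_balanced_classifier(
        X.loc[usable], y.loc[usable], n_trees, balance, seed, positive="pCR"
    )
    log["n_excluded"] = n_excluded
    return ClassificationCPMFit(
        model=model,
        predictors=predictors,
        feature_names=tuple(X.columns),
        train_log=log,
    )


def predict_pscore(
    fit: ClassificationCPMFit,
    cohort: Cohort,
    scores: SignatureScores | None,
) -> PScore:
    """P-score = predicted pCR probability per sample; NaN where predictors
    are missing (logged)."""
    X, complete = design_matrix(cohort, scores, fit.predictors)
    X = X[list(fit.feature_names)]
    out = pd.Series(np.nan, index=X.index, name="p_score")
    if complete.any():
        proba = fit.model.predict_proba(X.loc[complete].to_numpy())
        pos = list(fit.model.classes_).index(fit.train_log.get("positive_class", "pCR"))
        out.loc[complete] = proba[:, pos]
    n_missing = int((~complete).sum())
    if n_missing:
        logger.info("predict_pscore: %d samples got missing P-scores", n_missing)
    return out


def cross_val_pscore(
    cohort: Cohort,
    scores: SignatureScores | None,
    predictors: PredictorSpec,
    folds: int = 10,
    n_trees: int = DEFAULT_N_TREES,
    balance: bool = True,
    seed: int = 0,
    outcome_column: str = "response",
) -> PScore:
    """Out-of-fold P-scores: each sample is scored by a model that never saw
    it, via stratified k-fold with down-sampling inside each training fold.

    This is the default provenance for predictability labels (avoids the
    optimism of in-sample predictions).
    """
    X, complete = design_matrix(cohort, scores, predictors)
    y = cohort.clinical.data[outcome_column]
    usable = complete & y.notna()
    Xu, yu = X.loc[usable], y.loc[usable]
    out = pd.Series(np.nan, index=X.index, name="p_score")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=_child_seed(seed, 2))
    for k, (tr, te) in enumerate(skf.split(Xu.to_numpy(), yu.to_numpy())):
        model, _ = _fit_balanced_classifier(
            Xu.iloc[tr], yu.iloc[tr], n_trees, balance, _child_seed(seed, 10 + k),
            positive="pCR",
        )
        proba = model.predict_proba(Xu.iloc[te].to_numpy())
        pos = list(model.classes_).index("pCR")
        out.loc[Xu.index[te]] = proba[:, pos]
    return out


# ---------------------------------------------------------------------------
# Survival CPMs
# ---------------------------------------------------------------------------


@dataclass
class SurvivalCPMFit:
    """A fitted survival CPM. P-score = risk score, higher = higher risk
    (shorter predicted survival); for Cox this is the linear predictor
    ``coefficient * score``."""

    kind: str  # "cox_univariate" | "survival_forest"
    score_name: str
    coefficient: float | None = None
    model: object | None = None
    train_log: dict = field(default_factory=dict)


def _survival_frame(cohort: Cohort, scores: SignatureScores) -> pd.DataFrame:
    clin = cohort.clinical.data
    for col in ("time", "event"):
        if col not in clin.columns:
            raise ValueError(f"cohort lacks a {col!r} column")
    df = pd.DataFrame(
        {
            "time": pd.to_numeric(clin["time"]),
            "event": pd.to_numeric(clin["event"]),
            "score": scores.reindex(clin.index).astype(float),
        },
        index=clin.index,
    )
    usable = df.notna().all(axis=1)
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info("survival fit: excluded %d samples with missing time/event/score", n_excluded)
    return df.loc[usable]


def fit_cox_cpm(cohort: Cohort, scores: SignatureScores) -> SurvivalCPMFit:
    """Univariate Cox proportional-hazards CPM (partial likelihood, Efron
    tie handling). Raises with zero events or on non-convergence."""
    df = _survival_frame(cohort, scores)
    n_events = int(df["event"].sum())
    if n_events == 0:
        raise ValueError("cannot fit a Cox model with zero events")
    fitter = CoxPHFitter()
    try:
        fitter.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as err:
        raise ValueError(f"Cox model failed to converge: {err}") from err
    coef = float(fitter.params_["score"])
    return SurvivalCPMFit(
        kind="cox_univariate",
        score_name=str(scores.name),
        coefficient=coef,
        model=fitter,
        train_log={"n": len(df), "n_events": n_events},
    )


def fit_survival_forest_cpm(
    cohort: Cohort,
    scores: SignatureScores,
    n_trees: int = DEFAULT_RSF_TREES,
    seed: int = 0,
) -> SurvivalCPMFit:
    """Random-survival-forest CPM; P-score = ensemble mortality prediction
    (higher = higher risk)."""
    df = _survival_frame(cohort, scores)
    if int(df["event"].sum()) == 0:
        raise ValueError("cannot fit a survival forest with zero events")
    y = Surv.from_arrays(event=df["event"].to_numpy().astype(bool), time=df["time"].to_numpy())
    model = RandomSurvivalForest(
        n_estimators=int(n_trees), random_state=_child_seed(seed, 3), n_jobs=1
    )
    model.fit(df[["score"]].to_numpy(), y)
    return SurvivalCPMFit(
        kind="survival_forest",
        score_name=str(scores.name),
        model=model,
        train_log={"n": len(df), "n_events": int(df["event"].sum()), "n_trees": int(n_trees)},
    )


def predict_risk(fit: SurvivalCPMFit, cohort: Cohort, scores: SignatureScores) -> PScore:
    """Risk-ranking P-score per sample (higher = higher predicted risk)."""
    s = scores.reindex(cohort.clinical.data.index).astype(float)
    if fit.kind == "cox_univariate":
        return pd.Series(fit.coefficient * s, index=s.index, name="p_score")
    if fit.kind == "survival_forest":
        out = pd.Series(np.nan, index=s.index, name="p_score")
        ok = s.notna()
        if ok.any():
            out.loc[ok] = fit.model.predict(s.loc[ok].to_numpy().reshape(-1, 1))
        return out
    raise ValueError(f"unknown survival CPM kind {fit.kind!r}")
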