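"""Per-sample signature scores and nearest-centroid molecular subtyping.

The signature scorer is a generic weighted mean of (optionally z-scored)
gene expression: ``score(s) = sum_g w_g * x~_g(s) / sum_g |w_g|`` over the
signature genes present in the matrix. It is a rank-preserving stand-in for
assay-specific recurrence-score formulas; externally computed scores can be
supplied instead via :func:`read_external_scores`.

Subtyping follows the nearest-centroid convention: expression restricted to
the centroid genes is median-normalised across the cohort (per-gene median
subtracted), each sample is Spearman-correlated with every centroid column,
and the sample is called as the subtype attaining the maximal correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_cohort import (
    CentroidProfiles,
    Cohort,
    ExpressionMatrix,
    GeneSignature,
    SUBTYPE_ORDER,
)

logger = logging.getLogger("appliscore")

#: Per-sample signature scores: a float Series indexed by sample id, whose
#: ``name`` attribute carries the signature name.
SignatureScores = pd.Series


@dataclass
class SubtypeCall:
    """Subtype assignments plus the full sample-by-subtype correlation table."""

    subtype: pd.Series  # sample -> called subtype
    correlation: pd.DataFrame  # samples x subtypes, Spearman coefficients

    def __post_init__(self) -> None:
        called = self.correlation.idxmax(axis=1)
        # the call must attain the row maximum (idxmax breaks ties first-wins,
        # as does the caller, so equality is exact here)
        row_max = self.correlation.max(axis=1)
        attained = self.correlation.to_numpy()[
            np.arange(len(self.subtype)),
            self.correlation.columns.get_indexer(self.subtype),
        ]
        if not np.allclose(attained, row_max.to_numpy()):
            raise ValueError("called subtype must attain the maximal correlation")
        del called


def _expression_of(cohort: Cohort | ExpressionMatrix) -> pd.DataFrame:
    if isinstance(cohort, ExpressionMatrix):
        return cohort.values
    if cohort.expression is None:
        raise ValueError("cohort has no expression matrix")
    return cohort.expression.values


def score_signature(
    cohort: Cohort | ExpressionMatrix,
    signature: GeneSignature,
    standardize: str = "zscore",
) -> SignatureScores:
    """Weighted-mean signature score per sample.

    With ``standardize="zscore"`` each gene is z-scored across samples before
    weighting (a zero-variance gene contributes 0, logged); with ``"none"``
    raw log2 intensities are used. Raises if no signature gene is present.
    """
    if standardize not in ("zscore", "none"):
        raise ValueError("standardize must be 'zscore' or 'none'")
    expr = _expression_of(cohort)
    present = [g for g in signature.genes if g in expr.index]
    logger.info(
        "score_signature[%s]: %d/%d signature genes present",
        signature.name, len(present), len(signature.genes),
    )
    if not present:
        raise ValueError(
            f"no gene of signature {signature.name!r} is present in the expression matrix"
        )
    weights = np.array(
        [signature.weights[signature.genes.index(g)] for g in present], dtype=float
    )
    x = expr.loc[present].to_numpy(dtype=float)
    if standardize == "zscore":
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=0, keepdims=True)
        flat = (sd == 0).ravel()
        if flat.any():
            logger.info(
                "score_signature[%s]: %d zero-variance genes contribute 0",
                signature.name, int(flat.sum()),
            )
        sd = np.where(sd == 0, 1.0, sd)
        x = (x - mu) / sd
        x[flat, :] = 0.0
    denom = np.abs(weights).sum()
    if denom == 0:
        raise ValueError("signature weights sum to zero in absolute value")
    scores = weights @ x / denom
    return pd.Series(scores, index=expr.columns, name=signature.name)


def read_external_scores(path: str | Path, name: str | None = None) -> SignatureScores:
    """Import externally computed per-sample scores (sample_id, score TSV/CSV).

    Cross-check hook for users who compute assay scores with dedicated
    packages rather than the generic scorer.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    s = df.iloc[:, 0].astype(float)
    s.index = s.index.astype(str)
    s.name = name or df.columns[0]
    return s


def _rank_zscore(arr: np.ndarray) -> np.ndarray:
    """Column-wise average ranks, standardised (mean 0, unit sd)."""
    ranks = pd.DataFrame(arr).rank(axis=0, method="average").to_numpy()
    mu = ranks.mean(axis=0, keepdims=True)
    sd = ranks.std(axis=0, ddof=0, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (ranks - mu) / sd


def assign_pam50(
    cohort: Cohort | ExpressionMatrix, centroids: CentroidProfiles
) -> SubtypeCall:
    """Call molecular subtypes by maximal Spearman correlation with centroids.

    Restricts to shared genes (>=2 required), subtracts each gene's median
    across all cohort samples, and correlates each sample's normalised
    vector with every centroid column using average ranks. Correlation ties
    are broken by the fixed subtype order of the centroid columns (logged).
    """
    expr = _expression_of(cohort)
    shared = [g for g in centroids.gene_ids if g in expr.index]
    logger.info("assign_pam50: %d/%d centroid genes present", len(shared), len(centroids.gene_ids))
    if len(shared) < 2:
        raise ValueError("need at least 2 shared genes for Spearman correlation")
    # keep canonical column order when the centroid file has the known names
    cols = list(centroids.subtype_names)
    if set(cols) == set(SUBTYPE_ORDER):
        cols = list(SUBTYPE_ORDER)
    sub = expr.loc[shared]
    normed = sub.sub(sub.median(axis=1), axis=0).to_numpy(dtype=float)
    cent = centroids.values.loc[shared, cols].to_numpy(dtype=float)

    zs = _rank_zscore(normed)  # genes x samples
    zc = _rank_zscore(cent)  # genes x subtypes
    corr = zs.T @ zc / len(shared)  # samples x subtypes (Spearman rho)
    corr_df = pd.DataFrame(corr, index=expr.columns, columns=cols)

    arr = corr_df.to_numpy()
    best = arr.argmax(axis=1)  # first max wins -> fixed-order tie break
    ties = (arr == arr.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        logger.info(
            "assign_pam50: %d samples had tied maximal correlations; "
            "fixed subtype order used", int(ties.sum()),
        )
    calls = pd.Series([cols[i] for i in best], index=expr.columns, name="subtype")
    return SubtypeCall(subtype=calls, correlation=corr_df)
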