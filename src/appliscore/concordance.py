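"""Effective-pair rules, Harrell concordance, and its per-sample decomposition.

A pair of survival records ``(t1, e1)`` and ``(t2, e2)`` is an *effective
comparison* — one whose survival ordering is determinable under right
censoring — in exactly three scenarios:

* ``e1 = e2 = 1`` (both experienced the event),
* ``t1 > t2`` with ``e1 = 0, e2 = 1`` (patient 1 censored after patient 2's
  event), and the mirror case ``t1 < t2`` with ``e1 = 1, e2 = 0``.

A concordant pair is one where the longer-surviving member has the lower
predicted risk. Risk ties count 0.5 (Harrell convention); a both-event pair
with exactly equal times is effective but outcome-tied and also counts 0.5.

The decomposition attributes each effective pair to both of its members:
``c_sample_i`` is the fraction (ties half-weighted) of sample *i*'s
effective comparisons that the model orders correctly. The
``n_effective``-weighted mean of the per-sample concordances recovers the
overall concordance exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("appliscore")


class SurvivalRecord(NamedTuple):
    """One right-censored survival observation."""

    time: float
    event: int  # 1 = event observed, 0 = censored


@dataclass
class ConcordanceDecomposition:
    """Overall concordance plus the per-sample effective-pair decomposition.

    ``c_sample`` is NaN for samples with no effective comparisons
    (``n_effective == 0``).
    """

    overall: float
    n_effective: pd.Series  # int per sample
    c_sample: pd.Series  # float per sample, NaN when undefined
    n_total_pairs: int
    n_effective_pairs: int
    n_concordant: float  # concordant + 0.5 * tied

    def __post_init__(self) -> None:
        assert int(self.n_effective.sum()) == 2 * self.n_effective_pairs


def is_effective_pair(a: SurvivalRecord, b: SurvivalRecord) -> bool:
    """Whether the survival ordering of two records is determinable."""
    a, b = SurvivalRecord(*a), SurvivalRecord(*b)
    if a.event == 1 and b.event == 1:
        return True
    if a.event == 0 and b.event == 1 and a.time > b.time:
        return True
    if a.event == 1 and b.event == 0 and a.time < b.time:
        return True
    return False


def pair_concordant(
    a: SurvivalRecord, b: SurvivalRecord, risk_a: float, risk_b: float
) -> str:
    """Classify an effective pair as 'concordant', 'discordant' or 'tied'.

    Concordant iff the longer-surviving member carries the lower risk.
    Equal risks are tied; a both-event pair with equal times is outcome-tied.
    """
    a, b = SurvivalRecord(*a), SurvivalRecord(*b)
    if not is_effective_pair(a, b):
        raise ValueError("pair_concordant() called on a non-effective pair")
    if a.time == b.time:  # only possible when both have events
        return "tied"
    if risk_a == risk_b:
        return "tied"
    longer_is_a = a.time > b.time
    lower_risk_is_a = risk_a < risk_b
    return "concordant" if longer_is_a == lower_risk_is_a else "discordant"


def concordance_decomposition(
    records: Sequence[SurvivalRecord] | pd.DataFrame,
    risks: Sequence[float] | pd.Series,
    sample_ids: Sequence[str] | None = None,
) -> ConcordanceDecomposition:
    """Overall concordance and sample-specific concordances in one pass.

    ``records`` may be a sequence of ``(time, event)`` or a DataFrame with
    ``time``/``event`` columns. Computation is a vectorised enumeration of
    all ordered pairs; overall = (concordant + 0.5*tied) / effective pairs.
    """
    if isinstance(records, pd.DataFrame):
        times = records["time"].to_numpy(dtype=float)
        events = records["event"].to_numpy(dtype=int)
        if sample_ids is None:
            sample_ids = list(records.index)
    else:
        times = np.array([r[0] for r in records], dtype=float)
        events = np.array([r[1] for r in records], dtype=int)
    n = len(times)
    if sample_ids is None:
        sample_ids = list(range(n))
    risks = np.asarray(risks, dtype=float)
    if len(risks) != n:
        raise ValueError("one risk per record required")

    t_i, t_j = times[:, None], times[None, :]
    e_i, e_j = events[:, None].astype(bool), events[None, :].astype(bool)
    r_i, r_j = risks[:, None], risks[None, :]

    effective = (
        (e_i & e_j)
        | (~e_i & e_j & (t_i > t_j))
        | (e_i & ~e_j & (t_i < t_j))
    )
    np.fill_diagonal(effective, False)

    outcome_tied = e_i & e_j & (t_i == t_j)
    risk_tied = r_i == r_j
    longer_i = t_i > t_j
    lower_risk_i = r_i < r_j
    concordant = effective & ~outcome_tied & ~risk_tied & (longer_i == lower_risk_i)
    tied = effective & (outcome_tied | risk_tied)

    # per-sample counts: each effective pair involves two samples, so row
    # sums over the full (symmetric) matrix attribute it to both members
    n_eff = effective.sum(axis=1)
    credit = concordant.sum(axis=1) + 0.5 * tied.sum(axis=1)

    n_eff_pairs = int(effective.sum()) // 2
    if n_eff_pairs == 0:
        raise ValueError("no effective pairs among the records")
    n_conc_pairs = concordant.sum() / 2 + 0.5 * (tied.sum() / 2)
    overall = float(n_conc_pairs / n_eff_pairs)

    with np.errstate(invalid="ignore"):
        c_sample = np.where(n_eff > 0, credit / np.maximum(n_eff, 1), np.nan)
    n_undefined = int((n_eff == 0).sum())
    if n_undefined:
        logger.info(
            "concordance_decomposition: %d samples have no effective comparisons",
            n_undefined,
        )
    return ConcordanceDecomposition(
        overall=overall,
        n_effective=pd.Series(n_eff, index=sample_ids, name="n_effective"),
        c_sample=pd.Series(c_sample, index=sample_ids, name="c_sample"),
        n_total_pairs=n * (n - 1) // 2,
        n_effective_pairs=n_eff_pairs,
        n_concordant=float(n_conc_pairs),
    )


def effective_fraction_filter(
    decomp: ConcordanceDecomposition,
    cohort_size: int | None = None,
    fraction: float = 0.2,
) -> pd.Series:
    """Boolean mask retaining samples with at least ``floor(fraction *
    cohort_size)`` effective comparisons (inclusive bound).

    With the default fraction 0.2 a cohort of 997 yields the threshold
    floor(199.4) = 199.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if cohort_size is None:
        cohort_size = len(decomp.n_effective)
    threshold = math.floor(fraction * cohort_size)
    mask = decomp.n_effective >= threshold
    mask.name = "retained"
    logger.info(
        "effective_fraction_filter: threshold %d comparisons; retained %d/%d samples",
        threshold, int(mask.sum()), len(mask),
    )
    return mask
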