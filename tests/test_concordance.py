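"""Effective-pair rules and the sample-specific concordance decomposition.

The brute-force oracle below enumerates all pairs with scalar logic written
directly from the effective-comparison definition; it is independent of the
vectorised implementation it checks.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import appliscore as ap
from appliscore.concordance import SurvivalRecord


# ---------------------------------------------------------------------------
# Independent O(n^2) oracle
# ---------------------------------------------------------------------------

def brute_force_decomposition(times, events, risks):
    """Scalar pair enumeration: overall, per-sample effective counts and
    per-sample concordances (ties counted half)."""
    n = len(times)
    n_eff = [0] * n
    credit = [0.0] * n
    total_eff, total_credit = 0, 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ti, ei, tj, ej = times[i], events[i], times[j], events[j]
            if ei == 1 and ej == 1:
                effective = True
            elif ei == 0 and ej == 1 and ti > tj:
                effective = True
            elif ei == 1 and ej == 0 and ti < tj:
                effective = True
            else:
                effective = False
            if not effective:
                continue
            if ei == 1 and ej == 1 and ti == tj:
                score = 0.5
            elif risks[i] == risks[j]:
                score = 0.5
            else:
                longer, shorter = (i, j) if ti > tj else (j, i)
                score = 1.0 if risks[longer] < risks[shorter] else 0.0
            n_eff[i] += 1
            n_eff[j] += 1
            credit[i] += score
            credit[j] += score
            total_eff += 1
            total_credit += score
    overall = total_credit / total_eff if total_eff else None
    c_sample = [c / m if m else None for c, m in zip(credit, n_eff)]
    return overall, n_eff, c_sample, total_eff


def random_survival_data(n, seed, censoring=0.3, with_ties=False):
    rng = np.random.default_rng(seed)
    times = rng.exponential(10.0, n)
    if with_ties:
        times = np.round(times, 0) + 1.0
    events = (rng.random(n) > censoring).astype(int)
    risks = rng.normal(0, 1, n)
    if with_ties:
        risks = np.round(risks, 1)
    return times, events, risks


# ---------------------------------------------------------------------------
# Effective-pair truth table and pairwise classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "a, b, expected",
    [
        ((5, 1), (3, 1), True),   # both experienced the event
        ((5, 0), (3, 1), True),   # censored after the other's event
        ((3, 1), (5, 0), True),   # mirror case
        ((2, 0), (3, 1), False),  # censored before the other's event
        ((5, 0), (3, 0), False),  # both censored
        ((3, 1), (3, 0), False),  # censored exactly at the event time
    ],
)
def test_effective_pair_scenarios(a, b, expected):
    assert ap.is_effective_pair(SurvivalRecord(*a), SurvivalRecord(*b)) is expected


@given(
    ta=st.integers(0, 6), tb=st.integers(0, 6),
    ea=st.integers(0, 1), eb=st.integers(0, 1),
)
@settings(derandomize=True)
def test_effective_pair_is_symmetric(ta, tb, ea, eb):
    a, b = SurvivalRecord(ta, ea), SurvivalRecord(tb, eb)
    assert ap.is_effective_pair(a, b) == ap.is_effective_pair(b, a)


@pytest.mark.parametrize(
    "risks, expected",
    [((0.2, 0.9), "concordant"), ((0.9, 0.2), "discordant"), ((0.5, 0.5), "tied")],
)
def test_pair_concordance_against_risks(risks, expected):
    a, b = SurvivalRecord(5, 1), SurvivalRecord(3, 1)
    assert ap.pair_concordant(a, b, *risks) == expected


def test_equal_event_times_are_outcome_tied():
    assert ap.pair_concordant(SurvivalRecord(3, 1), SurvivalRecord(3, 1), 0.1, 0.9) == "tied"


def test_pair_concordant_rejects_non_effective_pair():
    with pytest.raises(ValueError, match="non-effective"):
        ap.pair_concordant(SurvivalRecord(5, 0), SurvivalRecord(3, 0), 0.1, 0.9)


# ---------------------------------------------------------------------------
# Decomposition
# ---------------------------------------------------------------------------

class TestDecomposition:
    def test_perfect_ranking(self):
        records = [(1, 1), (2, 1), (3, 1)]
        decomp = ap.concordance_decomposition(records, [3.0, 2.0, 1.0])
        assert decomp.overall == 1.0
        assert (decomp.c_sample == 1.0).all()
        assert (decomp.n_effective == 2).all()

    def test_reversed_ranking(self):
        decomp = ap.concordance_decomposition([(1, 1), (2, 1), (3, 1)], [1.0, 2.0, 3.0])
        assert decomp.overall == 0.0

    def test_no_effective_pairs_rejected(self):
        with pytest.raises(ValueError, match="no effective pairs"):
            ap.concordance_decomposition([(1, 0), (2, 0)], [0.1, 0.2])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("with_ties", [False, True])
    def test_matches_brute_force_oracle(self, seed, with_ties):
        times, events, risks = random_survival_data(50, seed, with_ties=with_ties)
        decomp = ap.concordance_decomposition(
            pd.DataFrame({"time": times, "event": events}), risks
        )
        overall, n_eff, c_sample, total_eff = brute_force_decomposition(
            list(times), list(events), list(risks)
        )
        assert decomp.overall == overall
        assert decomp.n_effective_pairs == total_eff
        assert list(decomp.n_effective) == n_eff
        for got, want in zip(decomp.c_sample, c_sample):
            assert (want is None and np.isnan(got)) or got == want

    def test_matches_lifelines_on_tie_free_data(self):
        from lifelines.utils import concordance_index

        times, events, risks = random_survival_data(120, seed=5)
        decomp = ap.concordance_decomposition(
            pd.DataFrame({"time": times, "event": events}), risks
        )
        # lifelines scores "predicted survival"; higher risk = shorter survival
        expected = concordance_index(times, -risks, events)
        assert decomp.overall == pytest.approx(expected, abs=1e-12)

    def test_overall_invariant_to_monotone_risk_transform(self):
        times, events, risks = random_survival_data(80, seed=7)
        base = ap.concordance_decomposition(pd.DataFrame({"time": times, "event": events}), risks)
        warped = ap.concordance_decomposition(
            pd.DataFrame({"time": times, "event": events}), np.exp(3 * risks) + 5
        )
        assert base.overall == warped.overall
        pd.testing.assert_series_equal(base.c_sample, warped.c_sample)

    @given(seed=st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_weighted_mean_identity(self, seed):
        """The n_effective-weighted mean of sample concordances equals the
        overall concordance (attribution identity)."""
        times, events, risks = random_survival_data(30, seed, with_ties=True)
        if events.sum() < 2:
            events[:2] = 1
        decomp = ap.concordance_decomposition(
            pd.DataFrame({"time": times, "event": events}), risks
        )
        defined = decomp.c_sample.notna()
        weighted = (
            decomp.n_effective[defined] * decomp.c_sample[defined]
        ).sum() / decomp.n_effective.sum()
        assert weighted == pytest.approx(decomp.overall, abs=1e-12)
        assert decomp.n_effective.sum() == 2 * decomp.n_effective_pairs


class TestEffectiveFractionFilter:
    def _decomp_with_counts(self, counts):
        n = len(counts)
        return ap.ConcordanceDecomposition(
            overall=0.5,
            n_effective=pd.Series(counts),
            c_sample=pd.Series([0.5] * n, dtype=float),
            n_total_pairs=n * (n - 1) // 2,
            n_effective_pairs=int(sum(counts)) // 2,
            n_concordant=sum(counts) / 4,
        )

    def test_printed_cohort_threshold(self):
        # cohort of 997 at fraction 0.2 -> floor(199.4) = 199, inclusive
        decomp = self._decomp_with_counts([198, 199, 200, 1])
        mask = ap.effective_fraction_filter(decomp, cohort_size=997, fraction=0.2)
        assert list(mask) == [False, True, True, False]

    def test_threshold_is_inclusive(self):
        decomp = self._decomp_with_counts([2, 1, 3])
        mask = ap.effective_fraction_filter(decomp, cohort_size=10, fraction=0.2)
        assert list(mask) == [True, False, True]

    def test_full_fraction_boundary(self):
        decomp = self._decomp_with_counts([9, 11])
        mask = ap.effective_fraction_filter(decomp, cohort_size=10, fraction=1.0)
        assert list(mask) == [False, True]

    def test_invalid_fraction_rejected(self):
        decomp = self._decomp_with_counts([1, 1])
        with pytest.raises(ValueError, match="fraction"):
            ap.effective_fraction_filter(decomp, cohort_size=10, fraction=0.0)
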