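# Methods

## The two-model framework

For a biomarker applied to a benchmark cohort, `appliscore` fits two
models. The **CPM** (clinical outcome prediction model) maps a per-patient
signature score plus clinical covariates to the clinical outcome. The
**PPM** (predictability prediction model) is a meta-classifier: the CPM's
per-patient track record is converted into binary predictability labels,
and the PPM learns to predict those labels from clinical features. Its
positive-class probability — the C-score — estimates the probability that
the CPM's call for a patient is correct, i.e. the applicability of the
biomarker to that patient. The rationale is that biomarker validity is
itself patient-dependent and associated with observable clinical features
(ER status being the canonical example for recurrence-score assays).

Both the CPM (classification branch) and the PPM use a random-forest
backbone with a default of 10,000 trees; tree count is the only
hyperparameter we set, all others follow the library defaults. Any
probabilistic classifier satisfying the same predict-probability contract
can be substituted. Tests and the acceptance script use 200–500 trees; at
these problem sizes (n ≤ 2000, ≤ 12 encoded features) AUC differences
versus 10,000 trees are well below the decision thresholds involved, and
the smaller ensembles keep the full suite in the minutes range.

## Input handling

Expression matrices are genes-in-rows log2 intensities; probeset-level
rows are collapsed to genes by keeping, for each gene, the probeset with
the highest mean intensity across all samples. Ties on the mean keep the
probeset that appears first in file order (logged) — the convention is
ours; any fixed rule would do, but it must be deterministic. Cohorts are
the intersection of expression and clinical samples, ordered by the
clinical table, with dropped samples logged.

Missing clinical values are NaN (the literal level `missing` is normalised
on read). Models use listwise exclusion: samples missing any predictor are
excluded from fitting with a logged count and receive missing P-/C-scores
at prediction time. Categoricals are one-hot encoded against a declared
level dictionary (reference = first level) so that encoded columns are
identical between training and application cohorts; ordinal integer coding
is available per column for stage/grade.

## Signature scores and subtyping

The signature scorer is a generic weighted mean:
`score(s) = Σ_g w_g · x̃_g(s) / Σ_g |w_g|` over the signature genes present
in the matrix, where x̃ is the per-gene z-score across cohort samples
(default) or the raw intensity. It is a rank-preserving stand-in for
assay-specific formulas (the commercial recurrence-score arithmetic is
deliberately out of scope); externally computed scores can be imported via
`read_external_scores` and used everywhere a score Series is accepted.
A zero-variance gene contributes 0 under z-scoring (logged). Equal-weight
z-score signatures have cohort-mean zero by construction, and z-scoring
makes the score invariant to per-gene affine rescaling of the input.

Subtype calls: expression restricted to the centroid genes is
median-normalised across the cohort (per-gene median subtracted), each
sample is Spearman-correlated (average ranks) with each of the five
centroid columns, and the maximal correlation wins. Correlation ties are
broken by the fixed subtype order Basal, Her2, LumA, LumB, Normal
(logged). Note the median normalisation uses the *cohort* median, so calls
on a sample depend weakly on cohort composition — the same property the
standard centroid-subtyping procedure has.

## Class balancing and cross-validation

Imbalanced binary problems (pCR ≪ RD; predictability labels) are balanced
by randomly down-sampling the majority class to the minority size, once,
before fitting; every minority sample is retained and the discarded
majority samples are still scored at prediction time. The balanced counts
are recorded in the train log and asserted equal on every fit.

Cross-validated accuracy is the mean over (default) 10 repeats of
stratified 10-fold CV: down-sampling happens inside each training fold,
out-of-fold probabilities are pooled within a repeat, and one trapezoidal
AUC per repeat is computed from the pooled predictions. Fold assignment
depends only on the seed after a canonical sort of sample ids, so the
estimate is invariant to input row order. Stratification guarantees both
classes in every fold whenever each class has at least `folds` members.

Predictor importance is drop-column importance: the full-model CV AUC
minus the CV AUC of the model refit without the predictor, same seed. With
redundant predictors each copy shows near-zero drop — a known property of
the method, covered by a test rather than corrected.

## Predictability labels

*Classification*: predicted pCR iff P-score > 0.5 (strict: exactly 0.5
predicts RD); label positive iff prediction matches the observed response.
By default labels come from out-of-fold P-scores (`provenance =
"out_of_fold"`), because in-sample random-forest probabilities are
near-memorised and would label almost everyone correct; an `in_sample`
mode exists for parity with R-style forests whose training-set predictions
are out-of-bag.

*Survival*: the Cox (or survival-forest) risk ranking is decomposed into
per-patient concordances. Patients need at least ⌊0.2 · cohort size⌋
effective comparisons to be labelled (inclusive bound, floor — a
997-patient cohort yields threshold 199); among the retained, positive iff
c_sample strictly exceeds the overall concordance (equality → negative).

Concordance conventions: risk ties count ½ (Harrell); a both-event pair
with exactly equal times is treated as effective but outcome-tied,
contributing ½ regardless of risks (the three effectiveness scenarios do
not address exact time ties; this choice keeps the decomposition identity
exact and is logged). "Longer predicted survival" means lower Cox linear
predictor / lower ensemble mortality; direction is part of the fit
contract. The decomposition satisfies
Σᵢ nᵢ·cᵢ = 2·(concordant + ½·tied), hence the weighted mean of the cᵢ
equals the overall C to 1e-12, which the suite asserts on random inputs
and against an independent brute-force enumerator.

## Accuracy–coverage curves

Patients are sorted by decreasing C-score (ties broken by sample id,
logged); `cumulative[N]` is the mean outcome metric (correctness indicator
or c_sample) over the top N patients, so `cumulative[1]` is the top
patient's metric and `cumulative[last]` the overall mean. Smoothing is a
centred moving average with the window truncated at the edges; defaults
are window 20 for classification and 200 for survival. When C-scores are
produced in-sample (PPM applied to its own training cohort) the top of the
curve is optimistic — the worked example's 100% top decile reflects this;
cross-cohort application (train on one cohort, curve on another, as the
CLI's train/apply separation supports) is the honest deployment readout.

## Synthetic cohorts

The generator plants the framework's premise — a biomarker valid only in a
covariate-defined stratum — with these defaults:

| parameter | default | meaning |
|---|---|---|
| n | 1000 | cohort size |
| applicable_fraction | 0.5 | P(ER-positive) = P(applicable stratum) |
| effect_beta | 2.0 | log-odds (or log-hazard) per unit score, inside stratum |
| prevalence | 0.25 | target pCR rate (imbalanced, as in real neoadjuvant data) |
| baseline_hazard | 0.1 | exponential event rate outside the stratum |
| censoring_rate | 0.05 | exponential censoring rate (≈ 30% censored) |

Covariates: age ~ N(55, 10); stage 3 levels (0.3/0.5/0.2); subtype 5
levels; score ~ N(0, 1). The classification intercept is calibrated *per
stratum* (bisection on the realised latent terms) so that both strata hit
the target prevalence: with a single global intercept the applicable
stratum would be pCR-richer, and CPM correctness outside the stratum would
be driven by majority-class guessing rather than by applicability — the
contrast the generator exists to plant. Survival times are exponential
with hazard `baseline_hazard · exp(beta·score)` inside the stratum,
independently exponentially censored.

What the generator does *not* emulate: covariate correlations of real
cohorts (age/stage/subtype are independent here), informative censoring,
batch effects, and any direct covariate→outcome effects besides the
stratum interaction. Passing tests therefore demonstrate that the
machinery recovers planted structure, not that any particular assay is
applicable to any particular population.

Two quantitative consequences of this design are worth knowing. First,
with effect_beta = 2 the CPM's in-stratum out-of-fold accuracy is ≈ 0.75
(the outcome stays stochastic), so the PPM — which sees a single binary
applicability feature — faces class-conditional correctness rates of
roughly (0.75, 0.50) and is information-theoretically capped near AUC 0.63
(two-point ROC); measured 10-fold CV AUC is ≈ 0.57, while the C-score-sorted
decile contrast remains large (≈ 0.35). Second, in the survival branch the
pairwise decomposition lets non-applicable patients inherit ordering
signal from applicable partners, so the well/poor contrast between strata
(≈ 0.59 vs 0.42) is weaker than the classification analogue. Both numbers
are recomputed, not asserted, by `scripts/acceptance.py`.

## Numerical and design choices

* Cox fits use the partial likelihood with Efron tie handling (lifelines);
  zero events or non-convergence raise. The survival-forest alternative
  uses 500 trees by default.
* Seeds: every randomised operation takes an explicit integer seed; child
  seeds are derived with a fixed LCG-style map and stay below 2³¹. No
  global random state is touched.
* Down-sampling happens once before fitting, not per tree.
* CPM and PPM may share predictors; no deduplication is attempted (the
  overlap is a property of the available clinical variables, and the two
  models answer different questions).
* Degenerate inputs fail loudly: empty expression files, duplicate sample
  headers, non-numeric cells (located by row/column), undeclared
  categorical levels, zero signature genes present, single-class training
  sets, no effective pairs.

## Known limitations

* The generic signature scorer preserves ranks, not assay units; analyses
  that need calibrated recurrence scores must import them.
* Drop-column importance underestimates redundant predictors.
* C-scores are raw forest probabilities, not recalibrated; threshold
  interpretations (e.g. "C-score > 0.8 = high confidence") should be
  validated per cohort.
* The survival PPM's separation is intrinsically limited by the pairwise
  mixing described above; a regression-on-c_sample variant is out of scope.
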