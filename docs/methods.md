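# Methods

This note documents the models and procedures implemented in `gmdhscreen`,
the defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions.

## Outcomes and measurement categorization

The seven ordinal symptom items drive five outcomes.  Binary:
*mild-to-moderate emotional symptoms* (≥ 3 of items 1–5 at
once-a-week-or-higher frequency), *depression* (item 6 positive),
*worriedness* (item 7 at "most of the time" or "always", the item wording
carrying the sleep-prevention qualifier), and *psychiatric symptoms* (the
union).  The three-class *extended* outcome standardizes the seven
un-dichotomized item codes, extracts the first principal component
(correlation-matrix PCA, sign oriented so higher score = higher burden) and
splits subjects at the tertiles.  Tertile cuts are the scores at ranks
⌈n/3⌉ and ⌈2n/3⌉; subjects tied with a cut value go to the lower group, so
the labeling is deterministic and independent of row order.

Measurement categorization uses fixed clinical cut points rather than
data-driven binning — every boundary is published, so a data-driven
discretizer would only add variance.  Conventions for printed bands that
overlap: sleep is the partition [0,5], (5,8], (8,∞) hours; birth-weight
boundaries 2500 g and 4000 g belong to the normal band (the outer bands are
printed strictly); family size ≤ 4 vs > 4; life satisfaction < 6 is low;
waist/height strictly greater than 0.5 is abdominal obesity.  The exact
response scale of the symptom items is not published beyond its endpoints;
the five ordinal labels used here (never … every day; never … always) are
declared in the packaged `schema.yaml` and are configurable.  BMI category
is consumed as given — computing it against a growth reference is out of
scope.

## Weight-of-evidence encoding

For each categorical feature and binary outcome, category c maps to
`ln[(e_c+s)/(E+sK)] − ln[(n_c+s)/(N+sK)]` with smoothing s = 0.5
(Haldane-style), K categories, e/n event/non-event counts.  s = 0.5 keeps
empty cells finite while changing well-populated cells negligibly.  WoE
maps are always fitted on training rows only and refitted inside every
cross-validation fold — the encoding sees the outcome, so a single global
fit would leak test labels into the covariates.

## Stability feature selection

B = 100 half-samples (complementary pairs), an L1-penalized logistic path
of 20 geometrically spaced penalties per half-sample, selection threshold
π = 0.6 on the per-penalty selection frequency maximized over admissible
penalties.  Two guards make the procedure honest about noise:

- **Penalty floor.** The grid runs from the all-zero point down to the
  universal-threshold level √(2 ln p · m · ȳ(1−ȳ)) on the half-sample
  scale (m rows) — the score magnitude at which pure-noise features start
  entering the path.  Without the floor, the chance correlations of any
  fixed dataset are *stably* selected: they are properties of the data, not
  of the subsampling, so resampling cannot wash them out.
- **Model-size admissibility.** Only grid points whose average model size
  is at most q = ⌈√p⌉ count toward a feature's frequency, bounding false
  selections in the usual stability-selection sense.

With these defaults, three planted main effects of 1.0 log-odds among 22
noise features (n = 5,000) are selected with at most one false positive,
and outcome permutation selects nothing (both are asserted in the tests).
Frequencies depend on which rows land in which half-sample, so results are
invariant to feature order but not to row order.

## The GMDH network

Each neuron is the full quadratic in one input pair, fitted by ridge
regression on the estimation split; λ is searched over {0} ∪ 25 log-spaced
values in [1e−4, 1e2] (0 included so the well-conditioned unregularized
solution is reachable; rank-deficient λ = 0 fits are skipped).  The
training rows are split 75/25 (stratified, seeded) into estimation and
validation.

**Fitness.** For binary outcomes a neuron's decision cut is chosen on its
*estimation* scores (MCC-optimal threshold over all score midpoints) and its
fitness is the MCC of that fixed cut on the validation split.  Fitting the
cut on the estimation side is deliberate: the cut is a model parameter, and
assessing a fully fitted model on untouched validation data preserves the
overfitting penalty that the early-stopping rule relies on.  (Re-optimizing
the cut on validation inflates every candidate's fitness and lets networks
grow on pure noise.)  λ is tuned to maximize this validation fitness, with
ties toward smaller λ.  The three-class variant regresses the class index
{0, 1, 2}, predicts the nearest index, and uses macro-averaged F1.

**Growth and stopping.** Layer 1 fits one neuron per unordered feature pair
and retains the top 10 by validation fitness (ties broken by lexicographic
input indices; constant-output neurons are discarded).  Deeper layers pair
the previous layer's retained neurons and retain up to 10 candidates that
*strictly* beat the previous layer's best; when none does, growth stops and
the best neuron so far becomes the network output.  A cap of ⌈p/2⌉+1 layers
bounds the loop.  The final decision threshold of the network is then
chosen on the validation split to maximize MCC — the imbalance-aware choice
for converting the continuous polynomial output into labels.

**Interpretation.** The retained wiring is exported as a graph;
feature importance counts, per original feature, its direct appearances in
the neurons reachable from the output.

**Null behavior (known limitation).** One validation split serves λ tuning,
ranking, retention and stopping.  Selection therefore leaks information
into later layers: a layer-2 neuron that blends two retained (hence
validation-favored) parents tends to improve fit *to that same validation
set* even when the outcome is pure noise, so on permuted outcomes the
network usually grows 2–5 layers before stopping rather than halting after
one.  The growth is bounded and benign — the final validation MCC on
permuted outcomes stays below 0.15 at the study sizes used here — but
stopping depth itself should not be read as evidence of signal.  A
three-way split (tuning / selection / stopping) would remove the leak at
the cost of data; it is deliberately not done, to keep the published
protocol.

## Baselines

LDA (closed form; signed discriminant as score), RBF-SVM (C and γ tuned by
grid search — C ∈ {0.1,1,10,100}, γ ∈ {0.01,0.1,1,10} — on an internal
75/25 split by validation MCC, refit on the full training data; margin as
score), and an MLP with one hidden layer of 10 logistic units, plain
cross-entropy, early stopping on a 25% validation fraction (positive-class
probability as score).  Scores, never hard labels, feed the AUC.  All wrap
scikit-learn estimators behind the same fit/predict/decision-scores
contract as the GMDH classifier.

## Validation framework

Stratified k-fold (k = 3) by per-class seeded round-robin, the same test
folds for every classifier.  Reports come in two layouts: per-fold
mean ± SD, and pooled-confusion-matrix point estimates with 95% CIs —
Wilson for proportions, log-normal on ln(DOR) for the diagnostic odds
ratio, DP = (√3/π)·ln(DOR) transformed from the DOR interval,
Hanley–McNeil for the rank AUC, percentile bootstrap (2,000 resamples) for
association coefficients.  Undefined ratios (zero denominators) are
reported as flagged placeholders, never as 0.  Classifier comparison:
Cochran's Q on the correctness indicators, McNemar pairwise post-hocs
(exact binomial below 25 discordant pairs, continuity-corrected χ²
otherwise; the two agree within 0.01 at the switch point), Bonferroni
adjustment.  χ² tests are Pearson without continuity correction, which
reproduces the packaged tables' published p-values within rounding.

## Synthetic generator

Features are drawn independently from configured categorical marginals;
each binary outcome follows a logistic model with configured main effects
and pure pairwise interaction terms.  The intercept is calibrated by
bisection on the *exact* population prevalence — independence makes the
marginalization a small sum over the joint cells of the features that carry
effects — so the realized prevalence differs from the target only by
binomial noise.  Missingness is MCAR: each non-protected cell is deleted
independently.  A single seed drives counter-based substreams per stage
(features / each outcome / missingness), so stages are independently
reproducible and bit-for-bit deterministic.

Because the generative model is known, the Bayes-optimal deterministic
classifier is computable: the optimal rule thresholds the posterior, so
scanning prefix rules over cells sorted by posterior gives the exact
ceiling MCC.  The cross-validated network is required (in the acceptance
tests) to come within 0.05 of that ceiling on the planted-interaction
benchmark.

The survey emulation (`survey_generator_config`) uses the packaged cohort
tables' category shares as marginals and the cohort prevalences (23.7% /
20.1% / 11.1%) as targets, with modest main effects on the features whose
category shares differ most between outcome groups (life satisfaction,
self-rated health, age, sex, breakfast, sleep, screen time; 0.2–1.8
log-odds).  What it does **not** emulate: between-feature correlation
(features are independent by default), the cohort's real effect structure
(unknowable from marginal tables), item-level responses, and
non-random missingness.  Passing tests on this generator therefore show
that the pipeline recovers structure it is pointed at under survey-like
marginals and imbalance — not that it would reproduce the cohort's fitted
networks.

## Study sizes and numerical conventions

Simulation studies use: planted-interaction recovery — 20 seeded runs at
n = 5,000, interaction 2.0 log-odds, prevalence 0.2, 8 noise features;
Bayes-gap and AUC-ordering studies — single seeded 3-fold runs at n = 5,000
and 3,000; null control — 10 seeded runs permuting the recovery study's
outcome.  Intercept bisection runs to 1e−10; ridge systems are solved by
Cholesky with ill-conditioning treated as singular; MCC uses the
0-on-degenerate-denominator convention inside fitness sweeps but is flagged
undefined in reports; threshold ties resolve toward the larger cut, λ ties
toward the smaller value, ranking ties toward lexicographic input order.

The two cohort-table columns whose printed counts do not sum to the cohort
total (sweetened beverage and fast food against the mild-to-moderate
outcome) are shipped as printed and flagged
(`fixtures.KNOWN_INCONSISTENT`); consistency-dependent operations refuse
them.  The packaged performance table's DP column is reproducible from its
DOR column via DP = (√3/π)·ln(DOR) only for some rows (e.g. the depression
row prints DP 2.04 where the formula gives 2.65 from the same row's
Se/Sp-consistent DOR of 121.6); the standard formula is implemented and the
printed DP values are not chased.
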