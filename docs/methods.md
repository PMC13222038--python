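# Methods

## Recall coding and cleaning

Input is long-format recall-order data: one row per recalled item with its
1-based study position, grouped into sequences by participant × unit ×
timepoint and ordered by output position. Cleaning applies two rules before
any metric is computed:

- **Intrusions** (recalls of items not on the study list) carry no study
  position and are dropped; the transition chain bridges across them.
- **Repetitions** of an already-recalled item are removed, keeping the first
  occurrence. By default the chain also bridges across a removed repetition
  (`repeat_policy="bridge"`); the alternative reading — that a repetition
  interrupts the chain so no transition is formed across it — is available
  as `repeat_policy="break"`. Bridge is the default because "ignoring" a
  repetition most plainly means deleting it from the order coding.

A sequence that cleans to fewer than two items is valid but unscoreable:
its score is carried as an explicit missing value (never as 0) and it is
excluded from score-level models while still contributing item-level
outcomes to the recall-accuracy models.

## Temporal organization score

For the k-th transition (from item *i* to item *j*), the available set is
every study position not yet recalled. Distances |p − i| for p in that set
are reverse-ranked — the smallest distance receives the largest rank N, and
tied distances share the mean of their ranks — and the transition scores
(R − 1)/(N − 1), where R is the rank of the actual distance |j − i|. In
closed form R = N − #{d < |j−i|} − (#{d = |j−i|} − 1)/2, which the
implementation uses instead of a sort. The per-sequence score is the mean
over transitions with defined percentiles.

Degenerate cases: when only one item remains available (the final forced
recall of a complete list), (R−1)/(N−1) is 0/0; that transition is
uninformative and is excluded from the average. A percentile of exactly 1
(0) occurs only when the actual distance is the strict minimum (maximum) of
the available distances.

Under uniformly random recall orders the expected score is .5, which is the
chance level against which the one-sample t tests compare.

## Lag-CRP

For each transition and each signed lag ℓ with |ℓ| ≤ 5, the possibility
count for ℓ increments when (current item + ℓ) is on the list and not yet
recalled; the occurrence count for the actual lag increments when |lag| ≤ 5.
Denominators open only at steps where a transition was actually made, and a
transition whose true |lag| exceeds the window still contributes to the
possibility counts of in-window lags but to no occurrence bin. CRP(ℓ) =
occurred/possible, undefined (missing, not 0) when a lag was never
possible. The window ±5 matches the convention that longer transitions are
too rare to estimate; it is configurable (`max_lag`).

Pooling sums occurrence and possibility counts before dividing; a
mean-of-per-unit-CRPs variant is provided for plotting, since the two
aggregates differ when denominators vary across units.

## Synthetic cohorts

The generator emulates the motivating study design: two groups of 60
participants ("NC", "TBI"), four narrative units of (10, 11, 12, 10) details
recalled at No/Short/Long Delay, and a 15-item wordlist recalled at
Trial 1, Trial 5 and after a short delay. Per condition (group × task ×
timepoint) three parameters apply:

- `p_recall` — per-item recall probability; the number recalled is
  k ~ Binomial(n_items, p_recall) conditioned on k ≥ 1 (every sequence has
  at least one recall; k = 1 sequences are kept to exercise the
  missing-score path).
- `tau` — temperature of the contiguity kernel. After recalling item *i*,
  the next item *j* is drawn from the remaining items with weight
  exp(−|j−i|/τ) × (φ if j > i else 1). τ = 0 is the deterministic
  nearest-available limit (forward preferred at ties); τ = ∞ is uniform.
  The first item is uniform (no primacy model) unless `force_start` pins it
  for limit-case tests.
- `phi_fwd` ≥ 1 — forward-bias multiplier producing the forward asymmetry.

This exponential kernel is the simplest generator with a single clustering
parameter; it is *not* a full retrieved-context (context-drift) model — it
has no primacy/recency structure, no semantic similarity, and no
learning-across-trials dynamics (Trial 1 vs Trial 5 is emulated purely by
different (p_recall, τ)). Passing tests therefore demonstrate that the
pipeline recovers clustering strength, forward bias, recall rates and their
group/timepoint contrasts from data with this structure — not that real
recall data satisfies the kernel.

Default condition tables encode the qualitative effects of interest, chosen
once as plausible magnitudes for this kind of study: TBI τ exceeds NC τ in
every condition and TBI p_recall sits ≈0.6 logits (narrative) / ≈0.9 logits
(wordlist) below NC; the Long Delay raises τ and lowers p_recall for both
groups; wordlist Trial 5 lowers τ and raises p_recall relative to Trial 1;
φ = 2.5 everywhere. Randomness is fully seeded: each sequence draws from a
substream keyed on (seed, group, participant, unit, timepoint), so cohorts
are bit-reproducible and stable under partial generation.

## Inference

All models are fixed-effects maximum-likelihood fits; within-participant
dependence is handled by a nonparametric cluster bootstrap that resamples
participants with replacement keeping all their rows (default B = 1000,
seeded). Bootstrap SEs feed normal-approximation p-values, and percentile
95% CIs are reported alongside; with B = 0 the model-based SEs are used.
This replaces random-intercept mixed modelling: it is implementable from
first principles and respects the clustering, at the cost of a different
small-sample df convention — statistics are comparable to mixed-model
output in sign and magnitude, not digit-for-digit.

Dummy coding fixes reference levels at NC (group), No Delay (narrative
timepoint) and Trial 5 (wordlist timepoint), so main effects read as simple
effects at the reference condition. `recode_reference` re-bases a factor
and refits to probe simple effects at other levels; this is a pure
reparameterization (log-likelihood and fitted values unchanged to 1e-8
relative, enforced by tests).

- **Recall accuracy**: logistic regression of the per-item binary outcome on
  group × timepoint. Complete separation is detected (constant response, or
  |coefficient| > 12 after fitting) and raised as an error naming the term.
- **Scores**: OLS on defined scores, group × timepoint; the covariate
  variant adds grand-mean-centered percent recall additively. Rank-deficient
  designs raise an error listing aliased columns (QR with pivoting).
- **Zero-inflated beta regression** for CRP values on group × timepoint ×
  |lag| × direction (direction coded backward = −.5, forward = +.5).
  Structurally impossible cells (possible = 0) are excluded — an impossible
  transition is not an observed zero — and CRPs of exactly 1 are adjusted
  to .999 before fitting (a third one-inflation component is deliberately
  not modelled; ones are rare in this design). The likelihood factorizes:
  the zero part P(y = 0) is a logit model fit by Newton/IRLS; the positive
  part is Beta(μφ, (1−μ)φ) with logit link on μ by default (`log`
  selectable, with μ clamped below 1) and constant φ, maximized by L-BFGS-B
  with analytic gradients. log φ is bounded in [log 0.01, log 1e6] so a
  zero-variance positive part terminates at the bound rather than
  diverging. SEs come from the observed information (central differences of
  the analytic gradient); φ's SE uses the delta method. Non-convergence
  raises an error with the gradient norm.

## Numerical and design choices

- Positions are 1-based throughout, matching how study orders are coded.
- Undefined quantities (scores with no scoreable transition, CRPs with an
  empty denominator) propagate as NaN and are dropped at model entry, never
  imputed.
- The beta part's mean link defaults to logit — the standard beta-regression
  choice — with `log` available because "log link on the magnitude" is a
  plausible alternative reading of the original analysis; both are tested.
- One-sample t tests use the classical statistic (scipy); a sample with
  zero variance is rejected as degenerate rather than returning ±∞.
- Report tables are written with fixed float formatting and stable row
  ordering so identical inputs yield byte-identical files.

## Problem sizes in the test suite

The acceptance-level tests run the pipeline at the scales the package's own
benchmarks specify: exhaustive brute-force comparison over all lists of up
to 6 items and recall orders of up to 4 items; 10,000 uniform recall orders
for the chance benchmark; 100 simulated cohorts at n = 200 per group
(narrative task) for the group-effect sign pattern; 100 cohorts at the
study's n = 60 per group for the repetition/delay directions; and n = 5,000
observations for zero-inflated-beta parameter recovery. Bootstrap-based
tests use smaller B (≈100–200) than the production default, which affects
only SE smoothness, not point estimates.

## Known limitations

- No true GLMM/random-effects estimation, and no automated random-effects
  selection; the cluster bootstrap is the only dependence correction.
- The generator cannot produce intrusions or repetitions itself (cleaning is
  exercised by hand-built fixtures), nor semantic clustering, serial-position
  effects, or cross-trial learning dynamics.
- Zero-one-inflated beta regression is intentionally out of scope; ones are
  handled by the .999 adjustment only.
- p-values from bootstrap SEs rely on a normal approximation; with few
  clusters they should be read qualitatively.
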