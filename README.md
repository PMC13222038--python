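# contiguity

Temporal-contiguity analysis of free recall: percentile-rank temporal
organization scores, lag-conditional response probabilities (lag-CRP), and
the group × timepoint inference stack used to compare clinical and
non-injured populations on narrative and wordlist recall tasks.

## The problem

When people retell a story or recall a wordlist, they tend to produce items
that were presented close together in time — the *temporal contiguity
effect* — with a bias toward forward transitions. In populations with
declarative-memory impairment (e.g. moderate-severe traumatic brain injury,
TBI), this temporal organization is reduced: recall jumps around the source
order. This package quantifies that organization from recall-order data and
tests how it differs by group and changes with delays and repetition.

Two measures are computed per participant × unit (story or list) × timepoint:

- **Temporal organization score.** Each successive recall pair is a
  transition with lag = (study position of the new item) − (study position
  of the previous item). The absolute lag is ranked against the distances of
  every item still available for recall, with the *smallest* distance
  receiving the *largest* rank N and tied distances sharing the mean rank.
  The transition's percentile is (R − 1)/(N − 1), and the score is the mean
  percentile over transitions: 1.0 = perfect temporal clustering, .5 =
  chance. Example: the recall order (2, 1, 4) on a 10-item list scores .90;
  (1, 5, 9) — in order but with big jumps — scores .38.
- **Lag-CRP.** For each signed lag ℓ ∈ {−5…−1, +1…+5}, the number of times
  an ℓ-transition occurred divided by the number of times it could have
  occurred given the list length and the items already recalled.

The inference stage mirrors a clinical two-group, multi-timepoint design:
one-sample t tests of scores against chance (.5); logistic models of
per-item recall; linear models of scores (optionally adjusting for
grand-mean-centered percent recall); and a **zero-inflated beta regression**
for CRP values (a logistic part for P(CRP = 0) and a beta part for positive
CRPs in (0, 1), with CRPs of exactly 1 adjusted to .999). Standard errors
respect within-participant dependence via a participant-cluster bootstrap.
A seeded synthetic-cohort generator with a one-parameter contiguity kernel
(weight ∝ exp(−|lag|/τ) × forward bias φ) makes the whole chain runnable and
testable without any participant data.

## Worked example

```python
from contiguity import StudyList, clean_recall, temporal_organization_score

study = StudyList("story", 10)
for order in [(2, 1, 4), (1, 5, 9), tuple(range(1, 11))]:
    seq = clean_recall(order, study)
    print(order, round(temporal_organization_score(seq, study).score, 2))
```

prints

```
(2, 1, 4) 0.9
(1, 5, 9) 0.38
(1, 2, 3, 4, 5, 6, 7, 8, 9, 10) 1.0
```

(2, 1, 4) makes two short transitions (lag −1, then +3), so it is highly
clustered even though it is not in serial order; (1, 5, 9) is in
chronological order but its large jumps rank poorly against the shorter
distances that were available; a strictly serial recall is perfect.

The numbered scripts under `analysis/` run the full study-scale pipeline on
a synthetic cohort (60 + 60 participants, four stories × 3 delays, one
15-word list × 3 trials):

```bash
python analysis/01_simulate_cohort.py   # writes results/synthetic/
python analysis/02_temporal_scores.py   # scores + chance tests
python analysis/03_lag_crp.py           # per-unit and pooled CRP curves
python analysis/04_fit_models.py        # all models, bootstrap SEs
```

With the default seed the cohort shows the built-in structure, e.g. mean
narrative scores of 0.876 (NC) vs 0.801 (TBI) at No Delay, dropping to
0.793 / 0.719 at the one-week delay; pooled narrative CRP of 0.537 at lag +1
vs 0.338 at lag −1 for NC (0.421 / 0.202 for TBI); every condition above
chance (largest chance-test p ≈ 7e-50); and the final script reports the
narrative group effect as `beta = -0.075, 95% CI [-0.091, -0.057]`.

A `contiguity` CLI (`simulate`, `score`, `crp`, `fit`, `report`) exposes the
same pipeline for CSV inputs; see `contiguity --help` for the schema.

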