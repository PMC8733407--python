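# Methods

## Problem setting

The package models early screening of aortic dissection (AD) from routine
clinical indexes in a severely imbalanced case-control population (about one
case per 65 controls). Its pipeline has four stages: univariate index
screening, cohort simulation (the raw hospital records are not public),
classifier training, and stratified evaluation in which control
false-positive rates are reported separately for patients with and without
chest pain — the symptom that dominates the differential diagnosis.

## Screening statistics

Continuous indexes are compared with a two-sample *t* statistic computed as
(control mean − case mean)/SE, so indexes elevated in cases have negative
sign. The default is the Welch unequal-variance form with
Welch–Satterthwaite degrees of freedom; this choice reproduces the published
vitals and blood-count statistics to two decimals at n = 802/52,411. A
pooled-variance variant is provided because the published age statistic
(15.03) follows the pooled formula instead — the source never names its
variant, so both are exposed (`test={"welch","pooled"}`). Coded indexes use
the Pearson chi-square on the levels-by-group count table with **no**
continuity correction (the corrected statistic does not match the published
values; the uncorrected one matches seven of them to two decimals).
P-values are two-sided *t* or upper chi-square tails; selection keeps
p ≤ α with α = 0.001 by default. No multiple-testing correction is applied —
the screening rule is a raw threshold by design.

A handful of published laboratory-index *t* values (e.g. D-dimer −5.49,
potassium 7.52) are not recoverable from the printed moments under either
variant at the full group sizes; the per-index measurement counts were
evidently smaller and are unreported. The package reproduces what the
printed inputs determine and makes no attempt to force those rows.

## Cohort simulator

Each feature is drawn independently given class: Gaussian with the published
class-conditional mean/SD for continuous indexes, Bernoulli with the
published prevalence for yes/no indexes, and a three-level categorical draw
for smoking status (no = 0, yes = 1, quit = 2). Class sizes are fixed by
design (`n_minority`, `imbalance_ratio`; defaults 802 and 65.35 echo the
source cohort of 802 vs 52,411), never sampled. Controls are stratified by
their simulated thoracalgia indicator. Missingness, when requested, is MCAR
at a uniform cell rate; imputation is column median (continuous) or mode
(coded, smallest value on ties).

What the simulator does **not** emulate: inter-feature correlation (only
marginal class-conditional moments are published, so features are
class-conditionally independent — real indexes such as the blood-count
percentages are strongly dependent), per-index measurement subsets,
longitudinal structure, and informative missingness. Consequently, passing
tests demonstrate correctness of the algorithms under the published
marginals, not clinical performance on real records; the simulated problem
is likely *easier* than the real one because independent features waste no
signal on redundancy.

Negative Gaussian draws for physically nonnegative indexes (durations,
counts) are kept by default so that sample moments converge to the nominal
parameters — several published SDs exceed their means (e.g. diabetes
duration 0.85 ± 2.87), so truncation at zero would shift those means by far
more than sampling error. An opt-in `clip_nonnegative=True` truncates at
zero when physically meaningful values matter more than moment fidelity.

## Ensemble

* Majority partition: seeded shuffle, ⌊|N|/|P|⌋ disjoint subsets of exactly
  |P|; leftover majority rows unused. Every base training set is exactly
  balanced.
* Base learner: AdaBoost (SAMME) over depth-1 decision stumps,
  50 boosting rounds by default; both configurable. The weak-learner depth
  and round count are conventional defaults — the source reports neither.
* Plain EasyEnsemble: `T_count="auto"` trains one base per majority subset,
  capped at 50 subsets to bound runtime at extreme imbalance.
* RS-EasyEnsemble: M = 20 bases by default (unreported in the source; even M
  enforced), each with its own feature subspace of ⌈fraction·d⌋ columns
  drawn without replacement, fraction 0.5 by default. If M exceeds the
  number of disjoint subsets available, subsets are reused cyclically.
* Best-half selection: the selection criterion is unreported; this package
  scores each base on a held-out stratified validation split (default 25% of
  the training cohort) by recall, tie-broken by accuracy and then base
  index, and keeps the top M/2. Recall is used because discovering the
  maximum number of cases is the stated objective of the design.
* Vote: the ensemble output Round((2/M)·Σ selected votes) is implemented as
  the half-up-rounded mean vote of the selected bases, in exact integer
  arithmetic (`2·votes ≥ n_selected`); a tied vote therefore predicts the
  positive class. With fraction = 1 and selection disabled this reduces
  bit-for-bit to plain EasyEnsemble majority voting, a tested invariant.
* An alternative reading of the design — selecting whole EasyEnsembles
  rather than individual base committees — is possible; the per-base reading
  of the published pseudocode is implemented.

All randomness (partition, subspaces, validation split, learner seeds) flows
from one integer seed through `numpy.random.default_rng`; identical
(data, config, seed) give identical models.

## Baselines

Trained deliberately on the raw imbalanced data with no reweighting — the
comparison's point is the imbalance pathology. LDA uses the least-squares
solver with automatic shrinkage fallback on singular scatter; ties in the
decision function resolve to the control class. The BP network is a
single-hidden-layer sigmoid network (default width 16; unreported in the
source) trained by full-batch gradient descent on the mean squared error
with a recorded loss trace, implemented directly in numpy because the
squared-error objective is part of the contract. The decision-tree method is
realised as a 100-tree random forest (the forest is named as the method's
realisation in the source). The SVM fixes C = 0.125, RBF kernel,
γ = 0.0078125, degree 3. Features are standardized (training-set mean/SD)
for LDA, BP and SVM; tree learners see raw values. The "80 input units" of
the source's network is interpreted as d, the surviving feature count, not a
hard-coded width.

## Evaluation

`tally` partitions a test set into the six stratified confusion cells;
accuracy, recall, ER_t and ER_nt are percent ratios as defined in the
README. A metric with an empty denominator is *not applicable* and reported
as NaN / "n/a", never coerced to 0 (a printed "0%" error rate means a zero
numerator, not an empty stratum). `compare_models` uses a stratified
75/25 train/test split by default — the source does not describe its split —
re-splitting and re-training per seed and averaging; split policy and seeds
are recorded on the report. Report percentages are formatted to two
decimals.

## Problem sizes and numerical choices

The packaged comparison runs (acceptance script, examples) use synthetic
cohorts of 300–400 cases at 1:65 imbalance — 20,000–26,000 rows — with
3–5 seeded replicates, sizes at which the qualitative ordering of the
methods is stable while a full run stays in the minutes range on one CPU.
Exact reproduction of the source's metric table is out of scope: it requires
the unavailable hospital records, and the simulator's independence
assumption changes the attainable operating points (the undersampling
ensembles reach higher recall here than reported on the real data).

Other numerical details: chi-square expected counts come from the margin
product over the grand total, with zero margins rejected as degenerate;
Welch t with both group variances zero is rejected rather than returned as
±inf; constant features screen to p = 1 with a warning; the sigmoid is
evaluated in the numerically stable split form; model files carry a format
version and refuse to load on mismatch.

## Known limitations

* Class-conditional independence in the simulator (see above) — the main
  gap between simulated and real difficulty.
* Calibration is out of scope: ensemble votes are not probabilities.
* The BP baseline's width, epochs and learning rate are documented defaults,
  not claimed faithful to the source's unreported settings.
* Screening treats coded features as categorical even when ordinal
  (smoking: no < yes < quit has no order in the chi-square).
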