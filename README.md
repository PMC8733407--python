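# adiag — imbalance-aware ensemble modelling for aortic-dissection screening

Aortic dissection (AD) is a rapidly fatal vascular emergency that first-line
clinics routinely miss: definitive imaging (CT angiography) is expensive and
slow, while the routine indexes a basic clinic *can* measure — vitals, blood
routine, coagulation, chemistry, plus coded history and complaint items —
carry a weak but real signal. The statistical obstacle is extreme class
imbalance: roughly one dissection per 65 control patients, a regime in which
ordinary classifiers buy accuracy by never predicting the positive class.

`adiag` implements the full auxiliary-diagnosis pipeline for this setting,
aimed at biostatisticians and ML practitioners working on rare-outcome
clinical tabular data:

- **Cohort simulator** — synthetic case-control tables with the published
  class-conditional marginals of the 40 screened clinical indexes
  (802 AD cases vs 52,411 controls; Gaussian per class for continuous
  indexes, Bernoulli / 3-level categorical for coded ones) at a configurable
  imbalance, with MCAR missingness and median/mode imputation.
- **Index screening** — Welch (or pooled) two-sample *t* and Pearson
  chi-square without continuity correction, computable from raw cohorts *or*
  directly from printed summary statistics, with the p ≤ 0.001 selection
  filter.
- **EasyEnsemble / RS-EasyEnsemble** — the undersampling ensemble at the
  package's core (below).
- **Baselines** — LDA, a back-propagation network (single hidden layer,
  squared-error loss), a random forest, and an RBF-SVM with the stated
  hyperparameters (C = 0.125, γ = 0.0078125).
- **Stratified evaluation** — the four headline metrics with false-positive
  rates reported separately for controls with and without chest pain.

## The core method

Let *P* be the minority (AD) set and *N* the majority set, |*P*| ≪ |*N*|.
EasyEnsemble partitions *N* by a seeded shuffle into disjoint subsets
*T₁…T_T* with |*Tᵢ*| = |*P*|, and trains an AdaBoost committee *Hᵢ* (depth-1
stumps) on each balanced set *Tᵢ* ∪ *P* — undersampling per learner without
discarding any majority data overall. RS-EasyEnsemble adds the random
subspace method and model selection: each of *M* bases is trained on a
random feature subset *Sᵢ* of size ⌈0.5·d⌋ drawn independently per base;
after training, the bases are scored on a held-out stratified validation
split (recall, then accuracy) and only the best *M*/2 are kept. The ensemble
predicts

  H(x) = Round( (2/M) · Σ_{i ∈ selected} Hᵢ(x) ),

i.e. the rounded mean vote of the selected half, with half-up rounding so a
tied vote resolves to the positive class — recall is the design priority.

Evaluation splits the test set six ways (TP/FN over cases; TN_t/FP_t over
controls with thoracalgia; TN_nt/FP_nt over controls without) and reports,
in percent:

  A = (TP + TN) / total, R = TP / (TP + FN),
  ER_t = FP_t / (TN_t + FP_t), ER_nt = FP_nt / (TN_nt + FP_nt).

## Worked example

`examples/train_rs_easyensemble.py` simulates the default cohort at 1:65
imbalance, trains RS-EasyEnsemble on a 75% stratified split and evaluates on
the rest:

```
trained M=20 bases on balanced sets of 450 rows each; 10 bases retained
test confusion: TP=93 FN=7 FP_t=116/1153 FP_nt=578/5347
accuracy 89.38%  recall 93.00%  ER_t 10.06%  ER_nt 10.81%
```

93 of 100 held-out dissections are caught (recall 93%), at the price of
flagging ~10% of controls — the intended trade-off for a screening tool
whose purpose is not to miss cases. Compare a single AdaBoost or the SVM on
the same raw imbalanced data (`examples/compare_five_models.py`): accuracy
near 98% with recall near 0 — the imbalance pathology the ensemble exists to
fix. The other examples recompute the published screening statistics from
summary data alone and re-screen a simulated cohort.

A thin CLI wraps the same library calls:

```sh
adiag simulate --n-minority 400 --ratio 65 --seed 7 -o cohort.csv
adiag screen cohort.csv -o screening.csv
adiag train cohort.csv --method rs-easyensemble --m 20 --seed 7 --model-out model.pkl
adiag compare cohort.csv --methods all --seed 1
```

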