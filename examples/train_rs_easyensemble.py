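"""Train RS-EasyEnsemble and read its stratified diagnostic report.

The ensemble partitions the majority class into balanced subsets, trains an
AdaBoost committee per subset on a random half of the feature space, keeps
the better half of the M committees by held-out recall, and predicts by a
rounded average vote. The metrics below follow the study's reporting
convention: recall over true cases, and separate false-positive rates for
controls with and without chest pain.
"""

from adiag import (accuracy, error_rate_nt, error_rate_t, generate_cohort,
                   recall, rs_easy_ensemble_fit, split_cohort, tally)

cohort = generate_cohort(n_minority=400, imbalance_ratio=65, seed=7)
train, test = split_cohort(cohort, test_size=0.25, seed=7)

model = rs_easy_ensemble_fit(train, M=20, subspace_fraction=0.5,
                             boosting_rounds=50, seed=7)
print(f"trained M={model.M} bases on balanced sets of "
      f"{2 * model.meta['P']} rows each; "
      f"{sum(b.selected for b in model.bases)} bases retained")

conf = tally(model.predict(test.X), test.labels, test.stratum)
print(f"test confusion: TP={conf.tp} FN={conf.fn} "
      f"FP_t={conf.fp_t}/{conf.fp_t + conf.tn_t} "
      f"FP_nt={conf.fp_nt}/{conf.fp_nt + conf.tn_nt}")
print(f"accuracy {accuracy(conf):.2f}%  recall {recall(conf):.2f}%  "
      f"ER_t {error_rate_t(conf):.2f}%  ER_nt {error_rate_nt(conf):.2f}%")

# High recall at the cost of some false positives is the intended trade-off:
# the model's job is to miss as few dissections as possible.
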