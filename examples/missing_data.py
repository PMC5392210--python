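"""Missing-data workflow: who completes more assessments, multiple
imputation of baseline predictors, Rubin pooling, and the concomitant-
variable sensitivity refit."""

import numpy as np
import pandas as pd

from ordlcga import (
    assessment_count_model, build_cohort, category_matrix, em_fit,
    generate_cohort, impute_exogenous, default_study_config, pool_rubin,
    sensitivity_refit,
)

# plant covariate-linked missingness: treated participants respond more
cfg = default_study_config(n=4000)
cfg.missingness_tilt = {"treatment": 1.0}
long_df, truth = generate_cohort(cfg, seed=9)
wide = build_cohort(long_df)

x = wide[["age", "treatment", "stress"]].apply(pd.to_numeric)
acm = assessment_count_model(x, wide["n_observed"])
print("logistic model of completing 3+ assessments:")
print(acm.round(3).to_string())
# the planted treatment effect (log odds 1.0) is recovered; age/stress ~ 0

# multiple imputation of predictor gaps + Rubin pooling of the age mean
holey = x.copy()
rng = np.random.default_rng(0)
holey.loc[rng.random(len(holey)) < 0.12, "stress"] = np.nan
imp = impute_exogenous(holey, m=10, seed=1)
est = np.array([[d["stress"].mean()] for d in imp.datasets])
var = np.array([[d["stress"].var(ddof=1) / len(d)] for d in imp.datasets])
pooled = pool_rubin(est, var)
print(f"\npooled stress mean over m={imp.m} imputations: "
      f"{pooled.loc[0, 'estimate']:.3f} (se {pooled.loc[0, 'se']:.3f}, "
      f"df {pooled.loc[0, 'df']:.0f})")

# sensitivity: regress class membership on the count-model predictors
y = category_matrix(wide)
fit = em_fit(y, 5, n_starts=10, n_final=4, seed=4)
sens = sensitivity_refit(y, fit, x[["treatment"]])
print("\nclass-proportion deltas after the concomitant-variable refit:")
print(np.round(sens["deltas"], 4))
# near-zero deltas = the class structure is robust to this missingness
# mechanism, which is the conclusion the check is designed to support.
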