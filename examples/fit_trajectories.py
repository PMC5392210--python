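"""Fit the 5-class ordinal growth mixture to a complete-data cohort and
compare the recovered class proportions with the generating truth."""

import numpy as np

from ordlcga import build_cohort, category_matrix, em_fit, generate_cohort, default_study_config
from ordlcga.experiments import match_classes

cfg = default_study_config(n=2000, apply_missingness=False)
long_df, truth = generate_cohort(cfg, seed=3)
wide = build_cohort(long_df)
y = category_matrix(wide)

fit = em_fit(y, k=5, n_starts=20, n_final=8, seed=11)
print(f"loglik {fit.loglik:.1f}; best solution replicated by "
      f"{fit.n_replicated} start(s); converged={fit.converged}")

perm = match_classes(fit.spec, cfg.spec)
print(f"\n{'class':<15}{'true pi':>9}{'estimated':>11}")
for i, name in enumerate(cfg.class_names):
    print(f"{name:<15}{cfg.spec.weights[i]:>9.3f}{fit.spec.weights[perm[i]]:>11.3f}")
# Proportions are recovered to within sampling error; intercept/threshold
# locations are reported in the anchored scale (middle threshold = 0) and
# can be shifted to any other anchor without changing the likelihood.
eta = fit.spec.eta_matrix()
print("\nestimated latent trajectories (eta by wave, anchored scale):")
for i, name in enumerate(cfg.class_names):
    print(f"{name:<15}" + " ".join(f"{v:7.2f}" for v in eta[perm[i]]))
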