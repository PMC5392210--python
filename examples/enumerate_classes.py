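"""Class enumeration: fit K = 1..4 to a 3-class cohort and read the
fit-statistic table the way the workflow intends (BIC/CAIC/AWE elbows,
approximate Bayes factors, cmP_A, entropy, and start replication)."""

import numpy as np

from ordlcga import ClassGrowthParams, MixtureSpec, enumerate_classes

classes = [
    ClassGrowthParams(-3.0, 0.5, np.array([0.0, 0.3, 0.5, 0.8, 1.0])),
    ClassGrowthParams(0.0, 2.5, np.array([0.0, 0.2, 0.5, 0.8, 1.0])),
    ClassGrowthParams(2.5, -3.0, np.array([0.0, 0.3, 0.6, 0.8, 1.0])),
]
spec = MixtureSpec(np.array([0.5, 0.3, 0.2]), classes, np.array([-2.5, 0.0, 2.5]))
rng = np.random.default_rng(21)
n = 1500
cls = rng.choice(3, size=n, p=spec.weights)
latent = spec.eta_matrix()[cls] + rng.logistic(size=(n, 5))
y = 1 + (latent[:, :, None] > spec.thresholds[None, None, :]).sum(axis=2)

res = enumerate_classes(y, k_max=4, seed=5, n_starts=10, n_final=4)
cols = ["K", "n_params", "loglik", "BIC", "CAIC", "AWE", "entropy", "cmP_A",
        "replicated"]
print(res.table[cols].round(2).to_string(index=False))
print(f"\nadvisory selection: K={res.recommended_k} "
      "(smallest BIC among replicated solutions)")
# BIC drops sharply up to the generating K and the elbow flattens beyond it;
# cmP_A concentrates on the best candidate; entropy near 1 means the
# posterior classification is clean.
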