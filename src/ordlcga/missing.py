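"""Missing-data machinery.

Three mechanisms drive missingness in sparse assessment cohorts: design
bucketing (few waves per participant), heterogeneity in how many assessments
a participant completes, and item-level gaps in baseline predictors.  This
module provides the corresponding diagnostics and corrections: a logistic
model of assessment count (2 vs 3+, or wave-by-wave response), chained-
equations multiple imputation of exogenous predictors with Rubin pooling,
and a sensitivity refit in which class membership is regressed directly on
missingness-related covariates inside the mixture likelihood (a concomitant-
variable model) so that maximum likelihood can absorb those mechanisms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import logsumexp

from .em import MixtureFit, _estep, _mstep, _pack, _spec_from_theta
from .model import MixtureSpec, _as_category_matrix, person_loglik_by_class

__all__ = [
    "assessment_count_model",
    "impute_exogenous",
    "ImputationSet",
    "pool_rubin",
    "sensitivity_refit",
]


def assessment_count_model(
    x: pd.DataFrame, n_assessments, *, wave_indicator=None
) -> pd.DataFrame:
    """Logistic regression of assessment intensity on baseline covariates.

    By default the outcome is the 3-or-more-assessments indicator (every
    included participant has at least 2).  Passing ``wave_indicator`` (a
    binary vector, e.g. responded at wave w) fits the wave-by-wave variant
    instead.  Returns a coefficient table with Wald tests; coefficients with
    exploding standard errors are flagged as separated.
    """
    if wave_indicator is not None:
        outcome = np.asarray(wave_indicator, dtype=float)
    else:
        n_assessments = np.asarray(n_assessments)
        if (n_assessments < 2).any():
            raise ValueError("all participants must have at least 2 assessments")
        outcome = (n_assessments >= 3).astype(float)
    if outcome.min() == outcome.max():
        raise ValueError("assessment-count outcome is constant; model is degenerate")
    xmat = sm.add_constant(x.astype(float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(outcome, xmat).fit(disp=False, maxiter=200)
    out = pd.DataFrame(
        {
            "coef": res.params,
            "se": res.bse,
            "p": res.pvalues,
            "odds_ratio": np.exp(res.params),
        }
    )
    out["separated"] = (out["se"] > 30) | ~np.isfinite(out["se"])
    return out


@dataclass
class ImputationSet:
    """m completed copies of a predictor table; observed cells identical."""

    datasets: list[pd.DataFrame]
    seed: int

    @property
    def m(self) -> int:
        return len(self.datasets)


def impute_exogenous(x: pd.DataFrame, m: int = 10, seed: int = 0,
                     n_burnin: int = 10) -> ImputationSet:
    """Chained-equations multiple imputation of a numeric predictor table.

    Uses predictive-mean-matching chained equations (statsmodels MICE), which
    draws donors from observed values so binary and categorical codes stay
    valid.  Columns are visited in ascending missingness order after
    ``n_burnin`` burn-in cycles.  Deterministic given ``seed``.
    """
    x = x.copy()
    frac = x.isna().mean()
    if (frac == 1.0).any():
        raise ValueError(f"all-missing column(s): {list(frac[frac == 1.0].index)}")
    high = frac[frac > 0.5]
    if len(high):
        warnings.warn(f"columns more than 50% missing: {list(high.index)}", stacklevel=2)
    if not x.isna().any().any():
        return ImputationSet([x.copy() for _ in range(m)], seed)

    from statsmodels.imputation.mice import MICEData

    order = list(frac.sort_values(kind="stable").index)
    np.random.seed(seed % (2**31))
    md = MICEData(x[order])
    for _ in range(n_burnin):
        md.update_all()
    datasets = []
    for _ in range(m):
        md.update_all()
        datasets.append(md.data[x.columns].copy().set_axis(x.index))
    obs = ~x.isna()
    for d in datasets:  # imputation must never touch observed cells
        if not ((d == x) | ~obs).all().all():
            raise AssertionError("imputation altered an observed cell")
    return ImputationSet(datasets, seed)


def pool_rubin(estimates, variances):
    """Rubin's rules for m sets of point estimates and squared SEs.

    Returns a DataFrame with the pooled point estimate (mean across
    imputations), total variance ``W + (1 + 1/m) B``, pooled SE, and the
    standard degrees of freedom ``(m - 1)(1 + W / ((1 + 1/m) B))^2``.
    """
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.ndim == 1:
        est, var = est[:, None], var[:, None]
    m = est.shape[0]
    if m < 2:
        raise ValueError("Rubin pooling needs m >= 2 imputations")
    point = est.mean(axis=0)
    within = var.mean(axis=0)
    between = est.var(axis=0, ddof=1)
    total = within + (1.0 + 1.0 / m) * between
    with np.errstate(divide="ignore"):
        r = (1.0 + 1.0 / m) * between / within
        df = np.where(between > 0, (m - 1) * (1.0 + 1.0 / r) ** 2, np.inf)
    return pd.DataFrame(
        {"estimate": point, "within_var": within, "between_var": between,
         "total_var": total, "se": np.sqrt(total), "df": df}
    )


# ---------------------------------------------------------------------------
# concomitant-variable sensitivity refit

def sensitivity_refit(
    data,
    fit: MixtureFit,
    covariates: pd.DataFrame | None,
    *,
    tol: float = 1e-8,
    max_iter: int = 300,
) -> dict:
    """Refit the mixture with class membership regressed on covariates.

    The class proportions pi_c are replaced by a multinomial-logistic prior
    pi_c(x_i) inside the likelihood (reference class = last), estimated
    jointly with the growth parameters by EM starting from the unconditional
    fit.  Returns the refit spec, the per-class mean prior proportions, and
    their deltas against the unconditional estimates — the sensitivity check
    for missingness-related covariates.
    """
    y = _as_category_matrix(data)
    n = len(y)
    k = fit.spec.n_classes
    anchor = fit.spec.anchor
    if covariates is None or (hasattr(covariates, "shape") and covariates.shape[1] == 0):
        base = fit.spec.weights
        return {
            "spec": fit.spec,
            "gamma": None,
            "proportions": base.copy(),
            "unconditional": base.copy(),
            "deltas": np.zeros(k),
            "loglik": fit.loglik,
            "converged": True,
        }
    xmat = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    d = xmat.shape[1]

    theta = _pack(fit.spec)
    gamma = np.zeros((k - 1, d))
    gamma[:, 0] = np.log(fit.spec.weights[:-1] / fit.spec.weights[-1])

    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        log_pi_i = _concomitant_logprior(gamma, xmat, k)
        ll_ic = person_loglik_by_class(y, _spec_from_theta(theta, fit.spec.weights, k, anchor))
        log_post = ll_ic + log_pi_i
        ll_i = logsumexp(log_post, axis=1)
        ll = float(ll_i.sum())
        r = np.exp(log_post - ll_i[:, None])
        if ll - prev < tol * (abs(prev) + 1.0) and prev > -np.inf:
            converged = ll >= prev - 1e-9
            break
        prev = ll
        # growth M-step via weighted category counts
        n_ctk = _counts_from_posterior(y, r, k)
        theta = _mstep(theta, n_ctk, k, anchor)
        # concomitant M-step: weighted multinomial logit with soft labels
        gamma = _fit_concomitant(gamma, xmat, r, k)

    log_pi_i = _concomitant_logprior(gamma, xmat, k)
    mean_prior = np.exp(log_pi_i).mean(axis=0)
    post_prop = r.mean(axis=0)
    spec = _spec_from_theta(theta, post_prop / post_prop.sum(), k, anchor)
    if not converged:
        warnings.warn("concomitant-variable refit did not converge", stacklevel=2)
    return {
        "spec": spec,
        "gamma": gamma,
        "proportions": post_prop,
        "mean_prior": mean_prior,
        "unconditional": fit.spec.weights.copy(),
        "deltas": post_prop - fit.spec.weights,
        "loglik": prev if prev > -np.inf else ll,
        "converged": converged,
    }


def _concomitant_logprior(gamma, xmat, k):
    lin = np.column_stack([xmat @ gamma.T, np.zeros(len(xmat))])
    return lin - logsumexp(lin, axis=1, keepdims=True)


def _counts_from_posterior(y, r, k):
    from .model import N_CATS, N_WAVES

    n_ctk = np.zeros((k, N_WAVES, N_CATS))
    for t in range(N_WAVES):
        obs = y[:, t] > 0
        if obs.any():
            np.add.at(n_ctk[:, t, :].T, y[obs, t] - 1, r[obs])
    return n_ctk


def _fit_concomitant(gamma0, xmat, r, k):
    d = xmat.shape[1]

    def negll(gflat):
        g = gflat.reshape(k - 1, d)
        log_pi = _concomitant_logprior(g, xmat, k)
        f = -float(np.sum(r * log_pi))
        pi = np.exp(log_pi)
        grad = -((r - pi)[:, :-1].T @ xmat).ravel()
        return f, grad

    res = minimize(negll, gamma0.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": 200, "ftol": 1e-12})
    return (res.x if res.fun <= negll(gamma0.ravel())[0] else gamma0.ravel()).reshape(
        k - 1, d
    )
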