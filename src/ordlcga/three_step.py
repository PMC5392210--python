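"""Manual 3-step auxiliary-variable analysis.

Step 1 fits the unconditional mixture; step 2 assigns each participant to
their modal class and quantifies the classification error of that assignment;
step 3 treats the modal label as a noisy indicator of the true latent class
— with measurement probabilities FIXED at the step-2 error rates — while
regressing class membership on covariates (multinomial logistic) or comparing
a distal outcome across classes.  Fixing the measurement part prevents the
auxiliary variables from distorting the trajectory classes themselves, and
corrects the attenuation that naive regression on modal labels suffers
whenever classification is imperfect.

When classification is perfect (identity error matrix) step 3 reduces
exactly to ordinary multinomial regression on the modal labels, which is the
oracle used in the tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = [
    "modal_assign",
    "classification_error",
    "ClassificationErrorMatrix",
    "step3_predictors",
    "step3_distal",
    "screen_predictors",
    "cohen_d",
    "standardize_predictors",
    "ThreeStepResult",
]

_LOGIT_FLOOR = 1e-12
_SENTINEL = np.log(_LOGIT_FLOOR)


def modal_assign(posterior: np.ndarray) -> np.ndarray:
    """Modal (highest-posterior) class per row, 0-based; exact ties break
    toward the lower class index."""
    p = np.asarray(posterior, dtype=float)
    return np.argmax(p, axis=1)


@dataclass
class ClassificationErrorMatrix:
    """q[s, c] = P(modal class = s | true class = c); columns sum to 1."""

    q: np.ndarray
    logits: np.ndarray  # log(q_sc / q_Kc), reference row = last class

    @property
    def n_classes(self) -> int:
        return self.q.shape[0]

    @classmethod
    def identity(cls, k: int) -> "ClassificationErrorMatrix":
        return classification_error_from_q(np.eye(k))


def classification_error_from_q(q: np.ndarray) -> ClassificationErrorMatrix:
    q = np.asarray(q, dtype=float)
    floored = np.maximum(q, _LOGIT_FLOOR)
    logits = np.log(floored) - np.log(floored[-1, :])
    return ClassificationErrorMatrix(q=q, logits=logits)


def classification_error(posterior: np.ndarray, modal=None) -> ClassificationErrorMatrix:
    """Average-posterior classification-error matrix.

    q_sc = sum_{i: modal_i = s} p_ic / sum_i p_ic.  An empty modal class
    leaves a zero row; the corresponding logits sit at the large-negative
    sentinel and a warning is emitted.
    """
    p = np.asarray(posterior, dtype=float)
    if modal is None:
        modal = modal_assign(p)
    modal = np.asarray(modal)
    k = p.shape[1]
    num = np.zeros((k, k))
    for s in range(k):
        sel = modal == s
        if sel.any():
            num[s] = p[sel].sum(axis=0)
        else:
            warnings.warn(f"modal class {s} is empty; its logits are sentinel-valued",
                          stacklevel=2)
    q = num / p.sum(axis=0)[None, :]
    return classification_error_from_q(q)


# ---------------------------------------------------------------------------
# step-3 multinomial prediction with fixed measurement error

@dataclass
class ThreeStepResult:
    """Coefficients, contrasts and/or distal comparisons from step 3."""

    error_matrix: ClassificationErrorMatrix
    reference: int | None = None
    coefficients: pd.DataFrame | None = None
    cov: np.ndarray | None = None
    contrasts: pd.DataFrame | None = None
    distal: pd.DataFrame | None = None
    distal_pairs: pd.DataFrame | None = None
    loglik: float | None = None
    class_names: list = field(default_factory=list)


def _design(x: pd.DataFrame | np.ndarray):
    if isinstance(x, pd.DataFrame):
        names = list(x.columns)
        arr = x.to_numpy(dtype=float)
    else:
        arr = np.asarray(x, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        names = [f"x{j}" for j in range(arr.shape[1])]
    return np.column_stack([np.ones(len(arr)), arr]), ["intercept"] + names


def _mn_negloglik(gamma_flat, xmat, logq_m, k, ref):
    """Negative log likelihood sum_i log sum_c softmax(gamma'x)_c q[m_i, c]
    and its analytic gradient over the free (non-reference) coefficient rows."""
    n, d = xmat.shape
    free = [c for c in range(k) if c != ref]
    gamma = np.zeros((k, d))
    gamma[free] = gamma_flat.reshape(k - 1, d)
    lin = xmat @ gamma.T                       # N x K
    log_s = lin - logsumexp(lin, axis=1, keepdims=True)
    log_terms = log_s + logq_m                 # N x K
    ll_i = logsumexp(log_terms, axis=1)
    r = np.exp(log_terms - ll_i[:, None])      # posterior true class
    s = np.exp(log_s)
    grad_gamma = (r - s).T @ xmat              # K x d
    grad = grad_gamma[free].ravel()
    return -float(ll_i.sum()), -grad


def step3_predictors(
    modal,
    error_matrix: ClassificationErrorMatrix,
    x,
    *,
    reference: int = 0,
    contrast_pairs: list[tuple[int, int]] | None = None,
    class_names: list | None = None,
) -> ThreeStepResult:
    """Regress latent class membership on covariates with fixed measurement
    error (step 3 of the manual 3-step procedure).

    ``x`` is a complete predictor table (standardize beforehand; see
    :func:`standardize_predictors`).  Coefficients are log odds versus the
    ``reference`` class; Wald p-values come from the observed-information
    covariance.  ``contrast_pairs`` lists (class_a, class_b) re-referencings
    whose coefficients are the differences of the reference-class log odds.
    """
    modal = np.asarray(modal)
    k = error_matrix.n_classes
    xmat, names = _design(x)
    n, d = xmat.shape
    logq = np.log(np.maximum(error_matrix.q, _LOGIT_FLOOR))
    logq_m = logq[modal, :]                    # N x K

    x0 = np.zeros((k - 1) * d)
    res = minimize(
        _mn_negloglik, x0, args=(xmat, logq_m, k, reference),
        jac=True, method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    est = res.x
    # Newton polish to a tight stationary point (backtracking line search)
    fun = lambda t: _mn_negloglik(t, xmat, logq_m, k, reference)
    f_cur, g_cur = fun(est)
    hess = _num_hessian(lambda t: fun(t)[1], est)
    for _ in range(20):
        if np.max(np.abs(g_cur)) < 1e-9:
            break
        try:
            step = np.linalg.solve(hess, g_cur)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        while scale > 1e-4:
            f_new, g_new = fun(est - scale * step)
            if f_new <= f_cur + 1e-12:
                est = est - scale * step
                f_cur, g_cur = f_new, g_new
                break
            scale /= 2
        else:
            break
        hess = _num_hessian(lambda t: fun(t)[1], est)
    cov, se = _cov_from_hessian(hess)

    free = [c for c in range(k) if c != reference]
    rows = []
    for j, c in enumerate(free):
        for m, name in enumerate(names):
            idx = j * d + m
            b = est[idx]
            s_ = se[idx]
            z = b / s_ if s_ > 0 else np.nan
            rows.append(
                {
                    "class": _cname(c, class_names),
                    "class_index": c,
                    "predictor": name,
                    "log_odds": b,
                    "se": s_,
                    "p": 2 * norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                    "odds_ratio": np.exp(b),
                    "estimable": bool(np.isfinite(s_) and s_ < 50),
                }
            )
    coef = pd.DataFrame(rows)

    contrasts = None
    if contrast_pairs:
        crows = []
        for a, b_cls in contrast_pairs:
            for m, name in enumerate(names):
                vec = np.zeros_like(est)
                if a != reference:
                    vec[free.index(a) * d + m] = 1.0
                if b_cls != reference:
                    vec[free.index(b_cls) * d + m] -= 1.0
                delta = float(vec @ est)
                var = float(vec @ cov @ vec)
                s_ = np.sqrt(var) if var > 0 else np.nan
                z = delta / s_ if s_ and s_ > 0 else np.nan
                crows.append(
                    {
                        "class": _cname(a, class_names),
                        "vs": _cname(b_cls, class_names),
                        "predictor": name,
                        "log_odds": delta,
                        "se": s_,
                        "p": 2 * norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                        "odds_ratio": np.exp(delta),
                    }
                )
        contrasts = pd.DataFrame(crows)

    return ThreeStepResult(
        error_matrix=error_matrix,
        reference=reference,
        coefficients=coef,
        cov=cov,
        contrasts=contrasts,
        loglik=-res.fun,
        class_names=list(class_names) if class_names else [],
    )


def _cname(c, class_names):
    return class_names[c] if class_names else f"class_{c + 1}"


def _num_hessian(grad_fn, x, h=1e-5):
    p = len(x)
    hess = np.zeros((p, p))
    for j in range(p):
        xp, xm = x.copy(), x.copy()
        step = h * max(1.0, abs(x[j]))
        xp[j] += step
        xm[j] -= step
        hess[:, j] = (grad_fn(xp) - grad_fn(xm)) / (2 * step)
    return 0.5 * (hess + hess.T)


def _cov_from_hessian(hess):
    """Covariance from a Hessian of a *negative* log likelihood."""
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    var = np.diag(cov).copy()
    se = np.sqrt(np.where(var > 0, var, np.nan))
    return cov, se


# ---------------------------------------------------------------------------
# step-3 distal outcome

def step3_distal(
    modal,
    error_matrix: ClassificationErrorMatrix,
    y,
    *,
    class_names: list | None = None,
    tol: float = 1e-10,
    max_iter: int = 2000,
) -> ThreeStepResult:
    """Class-specific means of a continuous distal outcome with fixed
    measurement error.

    The model is a normal mixture Y | C=c ~ N(mu_c, sigma_c^2) with free class
    proportions and the modal label as the fixed-error indicator; estimated by
    EM.  Missing outcomes contribute through the indicator only.  Reports
    pairwise mean differences with Wald p-values and Cohen's d pooled by
    effective-sample-size weighting.
    """
    modal = np.asarray(modal)
    y = np.asarray(y, dtype=float)
    k = error_matrix.n_classes
    obs = np.isfinite(y)
    logq_m = np.log(np.maximum(error_matrix.q, _LOGIT_FLOOR))[modal, :]

    # initialize from modal-group moments
    pi = np.bincount(modal, minlength=k).astype(float) + 1.0
    pi /= pi.sum()
    grand_m, grand_s = np.nanmean(y), max(np.nanstd(y), 1e-6)
    mu = np.array(
        [np.nanmean(y[modal == c]) if np.isfinite(y[modal == c]).any() else grand_m
         for c in range(k)]
    )
    sig = np.array(
        [max(np.nanstd(y[modal == c]), 0.1 * grand_s)
         if (np.isfinite(y[modal == c]).sum() > 1) else grand_s
         for c in range(k)]
    )

    prev = -np.inf
    for _ in range(max_iter):
        log_dens = np.zeros((len(y), k))
        log_dens[obs] = norm.logpdf(y[obs, None], mu[None, :], sig[None, :])
        log_post = np.log(pi) + logq_m + log_dens
        ll_i = logsumexp(log_post, axis=1)
        ll = float(ll_i.sum())
        r = np.exp(log_post - ll_i[:, None])
        if ll - prev < tol * (abs(prev) + 1.0) and prev > -np.inf:
            break
        prev = ll
        pi = np.maximum(r.sum(axis=0) / len(y), 1e-12)
        pi /= pi.sum()
        w = r[obs]
        wsum = np.maximum(w.sum(axis=0), 1e-12)
        mu = (w * y[obs, None]).sum(axis=0) / wsum
        sig = np.sqrt(np.maximum((w * (y[obs, None] - mu) ** 2).sum(axis=0) / wsum, 1e-12))

    n_eff = r[obs].sum(axis=0)
    # observed-information covariance over (pi logits, mu, log sig)
    theta = np.r_[np.log(pi[:-1] / pi[-1]), mu, np.log(sig)]
    grad_fn = lambda t: _distal_grad(t, y, obs, logq_m, k)
    hess = _num_hessian(grad_fn, theta)
    cov, se_all = _cov_from_hessian(hess)
    mu_cov = cov[k - 1 : 2 * k - 1, k - 1 : 2 * k - 1]

    distal = pd.DataFrame(
        {
            "class": [_cname(c, class_names) for c in range(k)],
            "mean": mu,
            "sd": sig,
            "proportion": pi,
            "n_eff": n_eff,
            "se_mean": se_all[k - 1 : 2 * k - 1],
        }
    )
    pooled_var = float(((n_eff - 1) * sig**2).sum() / max((n_eff - 1).sum(), 1e-12))
    pooled_sd = np.sqrt(pooled_var)
    rows = []
    for a in range(k):
        for b in range(k):
            if a == b:
                continue
            diff = mu[a] - mu[b]
            var = mu_cov[a, a] + mu_cov[b, b] - 2 * mu_cov[a, b]
            s_ = np.sqrt(var) if var > 0 else np.nan
            z = diff / s_ if np.isfinite(s_) and s_ > 0 else np.nan
            d_val = diff / pooled_sd if pooled_sd > 1e-10 else np.nan
            rows.append(
                {
                    "class": _cname(a, class_names),
                    "vs": _cname(b, class_names),
                    "mdiff": diff,
                    "se": s_,
                    "p": 2 * norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                    "cohen_d": d_val,
                }
            )
    pairs = pd.DataFrame(rows)
    return ThreeStepResult(
        error_matrix=error_matrix,
        distal=distal,
        distal_pairs=pairs,
        loglik=prev,
        class_names=list(class_names) if class_names else [],
    )


def _distal_grad(theta, y, obs, logq_m, k):
    """Analytic gradient of the distal-model negative log likelihood."""
    gamma = np.r_[theta[: k - 1], 0.0]
    pi = np.exp(gamma - logsumexp(gamma))
    mu = theta[k - 1 : 2 * k - 1]
    sig = np.exp(theta[2 * k - 1 :])
    log_dens = np.zeros((len(y), k))
    log_dens[obs] = norm.logpdf(y[obs, None], mu[None, :], sig[None, :])
    log_post = np.log(pi) + logq_m + log_dens
    ll_i = logsumexp(log_post, axis=1)
    r = np.exp(log_post - ll_i[:, None])
    g_gamma = (r.sum(axis=0)[:-1] - len(y) * pi[:-1])
    z = np.zeros((len(y), k))
    z[obs] = (y[obs, None] - mu[None, :]) / sig[None, :] ** 2
    g_mu = (r * z).sum(axis=0)
    zz = np.zeros((len(y), k))
    zz[obs] = ((y[obs, None] - mu[None, :]) ** 2 / sig[None, :] ** 2) - 1.0
    g_logsig = (r * zz).sum(axis=0)
    return -np.r_[g_gamma, g_mu, g_logsig]


# ---------------------------------------------------------------------------
# screening, standardization, effect size

def screen_predictors(
    modal,
    error_matrix: ClassificationErrorMatrix,
    candidates: pd.DataFrame,
    focal_pairs: list[tuple[int, int]],
    *,
    alpha: float = 0.01,
    reference: int = 0,
    class_names: list | None = None,
) -> list[str]:
    """One-at-a-time screen: each candidate enters a single-predictor step-3
    model and is retained when its p-value beats ``alpha`` on either focal
    contrast.  Retained variables enter the final model with no trimming."""
    keep = []
    for col in candidates.columns:
        res = step3_predictors(
            modal, error_matrix, candidates[[col]],
            reference=reference, contrast_pairs=focal_pairs, class_names=class_names,
        )
        sub = res.contrasts[res.contrasts["predictor"] == col]
        if (sub["p"] < alpha).any():
            keep.append(col)
    return keep


def standardize_predictors(
    x: pd.DataFrame, continuous: list[str], exclude: tuple = ("age", "sleep_hours")
) -> pd.DataFrame:
    """Divide continuous predictors by their (baseline analysis-sample) SD,
    excluding the named columns kept on their natural scale."""
    out = x.copy()
    for col in continuous:
        if col in exclude or col not in out.columns:
            continue
        sd = out[col].std(ddof=1)
        if sd > 0:
            out[col] = out[col] / sd
    return out


def cohen_d(group_a, group_b) -> float:
    """Standardized mean difference with df-weighted pooled SD."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled < 1e-12:
        return np.nan
    return float((a.mean() - b.mean()) / pooled)
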