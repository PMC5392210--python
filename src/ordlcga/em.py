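"""Maximum-likelihood estimation of the ordinal growth mixture by EM.

The E-step computes posterior class memberships; because the ordinal
likelihood factorizes over waves given class, its sufficient statistics
collapse to a (K, 5, 4) table of posterior-weighted category counts, so the
M-step cost is independent of sample size.  The M-step maximizes the expected
complete-data log likelihood over all growth parameters and the two free
thresholds jointly with L-BFGS-B and an analytic gradient (a generalized
M-step: any improvement of Q guarantees the observed-data log likelihood is
non-decreasing).  Response patterns are collapsed to unique rows with counts,
which makes cohorts of tens of thousands cheap to fit.

Multiple random starts guard against local optima; the best log likelihood,
and how many starts replicated it, are first-class outputs because
non-replication is the working criterion for an unstable solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import log_expit, logsumexp

from .model import (
    N_CATS,
    N_WAVES,
    ClassGrowthParams,
    MixtureSpec,
    _as_category_matrix,
    ordered_logit_logprobs,
)

__all__ = ["MixtureFit", "em_fit", "random_start", "order_classes", "estimate_se"]

#: parameter bounds on the anchored scale (tau_2 = anchor): generous enough
#: for curves whose category probabilities saturate, tight enough to keep
#: unidentified directions from wandering off.
_ALPHA_BOUND = 80.0
_BETA_BOUND = 80.0
_LOADING_BOUND = 30.0
_TAU_SPAN = 40.0
_TAU_GAP = 0.1


@dataclass
class MixtureFit:
    """A fitted mixture: estimates, posterior, and start bookkeeping."""

    spec: MixtureSpec
    loglik: float
    posterior: np.ndarray
    n_obs: int
    converged: bool
    seed: int
    n_starts: int
    n_replicated: int
    start_logliks: list = field(default_factory=list)
    degenerate: bool = False
    se: dict | None = None

    @property
    def n_params(self) -> int:
        return self.spec.n_params

    def modal(self) -> np.ndarray:
        """Modal class labels (0-based); ties break toward the lower index."""
        return np.argmax(self.posterior, axis=1)

    def to_dict(self) -> dict:
        d = {
            "spec": self.spec.to_dict(),
            "loglik": float(self.loglik),
            "n_obs": int(self.n_obs),
            "n_params": int(self.n_params),
            "converged": bool(self.converged),
            "seed": int(self.seed),
            "n_starts": int(self.n_starts),
            "n_replicated": int(self.n_replicated),
            "start_logliks": [float(x) for x in self.start_logliks],
            "degenerate": bool(self.degenerate),
        }
        if self.se is not None:
            d["se"] = {k: np.asarray(v).tolist() for k, v in self.se.items()}
        return d


# ---------------------------------------------------------------------------
# parameter vector <-> structured parameters

def _pack(spec: MixtureSpec) -> np.ndarray:
    parts = []
    for c in spec.classes:
        parts.extend([c.intercept, c.slope, *c.loadings[1:4]])
    parts.extend([spec.thresholds[0], spec.thresholds[2]])
    return np.asarray(parts, dtype=float)


def _unpack(theta: np.ndarray, k: int, anchor: float):
    g = theta[: 5 * k].reshape(k, 5)
    alpha, beta = g[:, 0], g[:, 1]
    lam = np.empty((k, N_WAVES))
    lam[:, 0] = 0.0
    lam[:, 1:4] = g[:, 2:5]
    lam[:, 4] = 1.0
    tau = np.array([theta[5 * k], anchor, theta[5 * k + 1]])
    eta = alpha[:, None] + beta[:, None] * lam
    return eta, tau, beta, lam


def _bounds(k: int, anchor: float):
    b = []
    for _ in range(k):
        b.append((-_ALPHA_BOUND, _ALPHA_BOUND))
        b.append((-_BETA_BOUND, _BETA_BOUND))
        b.extend([(-_LOADING_BOUND, _LOADING_BOUND)] * 3)
    b.append((anchor - _TAU_SPAN, anchor - _TAU_GAP))
    b.append((anchor + _TAU_GAP, anchor + _TAU_SPAN))
    return b


def _spec_from_theta(theta, pi, k, anchor) -> MixtureSpec:
    eta, tau, beta, lam = _unpack(theta, k, anchor)
    classes = [
        ClassGrowthParams(float(theta[5 * c]), float(beta[c]), lam[c].copy())
        for c in range(k)
    ]
    return MixtureSpec(np.asarray(pi, dtype=float), classes, tau, anchor=anchor)


# ---------------------------------------------------------------------------
# E-step on collapsed patterns

def _pattern_loglik_by_class(patterns: np.ndarray, logp: np.ndarray) -> np.ndarray:
    """(P, K) conditional log likelihoods from a (K, 5, 4) log-prob table."""
    p, k = patterns.shape[0], logp.shape[0]
    out = np.zeros((p, k))
    for t in range(N_WAVES):
        obs = patterns[:, t] > 0
        if obs.any():
            out[obs] += logp[:, t, patterns[obs, t] - 1].T
    return out


def _estep(patterns, counts, theta, log_pi, k, anchor):
    """Return (loglik, posterior over patterns, (K,5,4) weighted counts)."""
    eta, tau, _, _ = _unpack(theta, k, anchor)
    logp = ordered_logit_logprobs(eta, tau)
    ll_pc = _pattern_loglik_by_class(patterns, logp) + log_pi
    norm = logsumexp(ll_pc, axis=1, keepdims=True)
    loglik = float(np.dot(counts, norm[:, 0]))
    w = np.exp(ll_pc - norm) * counts[:, None]  # P x K effective weights
    n_ctk = np.zeros((k, N_WAVES, N_CATS))
    for t in range(N_WAVES):
        obs = patterns[:, t] > 0
        if obs.any():
            cats = patterns[obs, t] - 1
            np.add.at(n_ctk[:, t, :].T, cats, w[obs])
    return loglik, w, n_ctk


# ---------------------------------------------------------------------------
# M-step objective: expected complete-data negative log likelihood + gradient

def _log_sig_prime(x):
    return log_expit(x) + log_expit(-x)


def _q_neg(theta, n_ctk, k, anchor):
    eta, tau, beta, lam = _unpack(theta, k, anchor)
    logp = ordered_logit_logprobs(eta, tau)
    q = float(np.sum(n_ctk * logp))

    # gradient ratios sigma'(a)/P and sigma'(b)/P; bounded because threshold
    # gaps are bounded away from zero
    ga = np.zeros_like(logp)
    gb = np.zeros_like(logp)
    for cat in range(N_CATS):
        if cat >= 1:  # lower cut a = tau[cat-1] - eta
            ga[..., cat] = np.exp(
                np.clip(_log_sig_prime(tau[cat - 1] - eta) - logp[..., cat], None, 50)
            )
        if cat <= 2:  # upper cut b = tau[cat] - eta
            gb[..., cat] = np.exp(
                np.clip(_log_sig_prime(tau[cat] - eta) - logp[..., cat], None, 50)
            )

    dq_deta = np.sum(n_ctk * (ga - gb), axis=2)  # K x 5
    grad = np.zeros_like(theta)
    g = grad[: 5 * k].reshape(k, 5)
    g[:, 0] = dq_deta.sum(axis=1)
    g[:, 1] = (dq_deta * lam).sum(axis=1)
    g[:, 2:5] = beta[:, None] * dq_deta[:, 1:4]
    # free thresholds tau_1 and tau_3 (indices 0 and 2)
    for j, slot in ((0, 5 * k), (2, 5 * k + 1)):
        grad[slot] = float(
            np.sum(n_ctk[..., j] * gb[..., j]) - np.sum(n_ctk[..., j + 1] * ga[..., j + 1])
        )
    return -q, -grad


def _mstep(theta, n_ctk, k, anchor, maxiter=200):
    res = minimize(
        _q_neg,
        theta,
        args=(n_ctk, k, anchor),
        jac=True,
        method="L-BFGS-B",
        bounds=_bounds(k, anchor),
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
    )
    # generalized EM: never accept a Q decrease
    if res.fun <= _q_neg(theta, n_ctk, k, anchor)[0]:
        return res.x
    return theta


# ---------------------------------------------------------------------------
# starts

def random_start(seed: int, k: int, data, anchor: float = 0.0) -> MixtureSpec:
    """Deterministic seeded initial spec.

    Participants are partitioned by k-means on their (jittered) wave-by-wave
    category profiles; initial thresholds come from marginal category
    frequencies, initial growth curves from per-class mean categories mapped
    through those thresholds, and the whole parameter vector is then refined
    by a single complete-data M-step under the hard partition — which lets a
    start reach widely separated classes immediately.
    """
    y = _as_category_matrix(data)
    rng = np.random.default_rng(seed)
    obs = y > 0
    cats = np.where(obs, y, np.nan)
    mean_cat = np.nanmean(cats, axis=1)

    # marginal thresholds from cumulative category frequencies, anchored
    flat = y[obs]
    freq = np.array([(flat == c).sum() for c in range(1, N_CATS + 1)], dtype=float)
    freq = (freq + 1.0) / (freq.sum() + N_CATS)
    cum = np.cumsum(freq)[:3]
    tau = np.log(cum / (1 - cum))
    tau = np.maximum.accumulate(tau + 1e-6 * np.arange(3))
    for j in (1, 2):
        if tau[j] - tau[j - 1] < 2 * _TAU_GAP:
            tau[j] = tau[j - 1] + 2 * _TAU_GAP
    tau = tau - tau[1] + anchor

    if k == 1:
        assign = np.zeros(len(y), dtype=int)
        pi = np.array([1.0])
    else:
        from sklearn.cluster import KMeans

        profile = np.where(obs, cats, mean_cat[:, None])
        feats = profile + rng.normal(0, 0.4, profile.shape)
        km = KMeans(n_clusters=k, n_init=1, random_state=int(rng.integers(2**31)))
        assign = km.fit_predict(feats)
        share = np.bincount(assign, minlength=k) / len(y)
        pi = 0.9 * share + 0.1 / k
        pi = pi / pi.sum()

    # map a mean category in [1, 4] to a latent-response value
    anchors_eta = np.array(
        [tau[0] - 2.0, (tau[0] + tau[1]) / 2, (tau[1] + tau[2]) / 2, tau[2] + 2.0]
    )
    classes = []
    marginal_eta = np.interp(np.nanmean(cats), [1, 2, 3, 4], anchors_eta)
    for c in range(k):
        sel = assign == c
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m_t = np.nanmean(cats[sel], axis=0) if sel.any() else np.full(N_WAVES, np.nan)
        m_t = np.where(np.isnan(m_t), np.nanmean(mean_cat[sel]) if sel.any() else 2.0, m_t)
        eta_t = np.interp(m_t, [1, 2, 3, 4], anchors_eta)
        eta_t = np.where(np.isfinite(eta_t), eta_t, marginal_eta)
        alpha = float(eta_t[0])
        beta = float(eta_t[4] - eta_t[0])
        if abs(beta) > 0.2:
            lam_mid = np.clip((eta_t[1:4] - alpha) / beta, -2.0, 3.0)
        else:
            lam_mid = np.array([0.25, 0.5, 0.75])
        if k > 1:  # perturb everything but the single-class marginal start
            alpha += rng.normal(0, 0.25)
            beta += rng.normal(0, 0.25)
            lam_mid = lam_mid + rng.normal(0, 0.1, 3)
        classes.append(
            ClassGrowthParams(alpha, beta, np.r_[0.0, lam_mid, 1.0])
        )
    spec = MixtureSpec(pi, classes, tau, anchor=anchor)

    # refine by one complete-data M-step under the hard partition
    n_ctk = np.zeros((k, N_WAVES, N_CATS))
    for t in range(N_WAVES):
        sel = y[:, t] > 0
        if sel.any():
            np.add.at(n_ctk, (assign[sel], t, y[sel, t] - 1), 1.0)
    theta = _mstep(_pack(spec), n_ctk, k, anchor, maxiter=300)
    return _spec_from_theta(theta, pi, k, anchor)


# ---------------------------------------------------------------------------
# driver

def _run_em(patterns, counts, spec, tol, max_iter, mstep_iter=200):
    """Run EM from one start; returns (theta, pi, loglik, converged, n_iter)."""
    k = spec.n_classes
    anchor = spec.anchor
    theta = _pack(spec)
    pi = spec.weights.copy()
    n = counts.sum()
    prev = -np.inf
    converged = False
    for it in range(max_iter):
        loglik, w, n_ctk = _estep(patterns, counts, theta, np.log(pi), k, anchor)
        if it > 0 and loglik - prev < tol * (abs(prev) + 1.0):
            converged = loglik >= prev - 1e-9
            prev = loglik
            break
        prev = loglik
        pi = np.maximum(w.sum(axis=0) / n, 1e-300)
        pi = pi / pi.sum()
        theta = _mstep(theta, n_ctk, k, anchor, maxiter=mstep_iter)
    else:
        it = max_iter
    loglik, _, _ = _estep(patterns, counts, theta, np.log(pi), k, anchor)
    return theta, pi, loglik, converged, it


def em_fit(
    data,
    k: int,
    n_starts: int = 50,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_final: int = 20,
    short_iters: int = 25,
    anchor: float = 0.0,
    compute_se: bool = False,
) -> MixtureFit:
    """Fit a K-class ordinal growth mixture by multi-start EM.

    ``n_starts`` seeded starts are run for ``short_iters`` EM iterations; the
    ``n_final`` most promising are run to convergence (relative log-likelihood
    change below ``tol`` or ``max_iter``).  Starts converging to a degenerate
    solution (any class proportion below 0.5/N) are discarded as spurious
    unless nothing else remains.  All randomness derives from ``seed``.
    """
    y = _as_category_matrix(data)
    n = len(y)
    patterns, counts = np.unique(y, axis=0, return_counts=True)
    counts = counts.astype(float)
    if k > len(patterns):
        warnings.warn(
            f"requested {k} classes but only {len(patterns)} distinct response "
            "patterns: model is under-identified",
            stacklevel=2,
        )
    child_seeds = np.random.SeedSequence(seed).generate_state(max(n_starts, 1)) % (2**31)

    stage1 = []
    for s in child_seeds[:n_starts]:
        spec0 = random_start(int(s), k, patterns.repeat(counts.astype(int), axis=0), anchor)
        theta, pi, ll, _, _ = _run_em(
            patterns, counts, spec0, tol, short_iters, mstep_iter=60
        )
        stage1.append((ll, theta, pi))
    stage1.sort(key=lambda r: -r[0])

    finals = []
    for ll0, theta0, pi0 in stage1[: max(n_final, 1)]:
        spec0 = _spec_from_theta(theta0, pi0, k, anchor)
        theta, pi, ll, conv, _ = _run_em(patterns, counts, spec0, tol, max_iter)
        degen = bool(np.any(pi < 0.5 / n))
        finals.append((ll, theta, pi, conv, degen))

    clean = [f for f in finals if not f[4]]
    pool = clean if clean else finals
    pool.sort(key=lambda r: -r[0])
    best_ll, best_theta, best_pi, best_conv, best_degen = pool[0]
    n_replicated = sum(1 for f in pool if abs(f[0] - best_ll) < 1e-2)
    if best_degen:
        warnings.warn("best solution has a degenerate class (pi < 0.5/N)", stacklevel=2)

    spec = _spec_from_theta(best_theta, best_pi, k, anchor)
    fit = MixtureFit(
        spec=spec,
        loglik=best_ll,
        posterior=np.empty((0, k)),
        n_obs=n,
        converged=best_conv,
        seed=seed,
        n_starts=n_starts,
        n_replicated=n_replicated,
        start_logliks=[f[0] for f in pool],
        degenerate=best_degen,
    )
    fit = order_classes(fit)
    from .model import posterior as _posterior

    fit.posterior = _posterior(y, fit.spec)
    if compute_se:
        fit.se = estimate_se(fit, y)
    return fit


def order_classes(fit: MixtureFit) -> MixtureFit:
    """Relabel classes in decreasing proportion; ties break by ascending
    baseline linear predictor.  The likelihood is invariant to this."""
    spec = fit.spec
    pi = spec.weights
    base_eta = np.array([c.eta[0] for c in spec.classes])
    order = np.lexsort((base_eta, -np.round(pi, 12)))
    new_spec = MixtureSpec(
        pi[order],
        [spec.classes[i] for i in order],
        spec.thresholds.copy(),
        anchor=spec.anchor,
    )
    post = fit.posterior[:, order] if fit.posterior.size else fit.posterior
    return MixtureFit(
        spec=new_spec,
        loglik=fit.loglik,
        posterior=post,
        n_obs=fit.n_obs,
        converged=fit.converged,
        seed=fit.seed,
        n_starts=fit.n_starts,
        n_replicated=fit.n_replicated,
        start_logliks=fit.start_logliks,
        degenerate=fit.degenerate,
        se=fit.se,
    )


# ---------------------------------------------------------------------------
# observed-information standard errors

def _score(theta_full, patterns, counts, k, anchor):
    """Analytic score of the observed-data log likelihood.

    ``theta_full`` appends K-1 proportion logits (vs the last class) to the
    growth/threshold vector.  Uses the EM identity: the observed score equals
    the gradient of Q at the current parameters.
    """
    theta = theta_full[: 5 * k + 2]
    gamma = np.r_[theta_full[5 * k + 2 :], 0.0]
    log_pi = gamma - logsumexp(gamma)
    _, w, n_ctk = _estep(patterns, counts, theta, log_pi, k, anchor)
    _, neg_grad = _q_neg(theta, n_ctk, k, anchor)
    pi = np.exp(log_pi)
    n = counts.sum()
    grad_gamma = w.sum(axis=0)[:-1] - n * pi[:-1]
    return np.r_[-neg_grad, grad_gamma]


def estimate_se(fit: MixtureFit, data) -> dict:
    """Observed-information standard errors via a central-difference Hessian
    of the analytic score.  Entries are NaN where the information matrix is
    not positive definite in that direction."""
    y = _as_category_matrix(data)
    patterns, counts = np.unique(y, axis=0, return_counts=True)
    counts = counts.astype(float)
    k = fit.spec.n_classes
    anchor = fit.spec.anchor
    pi = fit.spec.weights
    gamma = np.log(pi[:-1] / pi[-1]) if k > 1 else np.empty(0)
    theta_full = np.r_[_pack(fit.spec), gamma]
    p = len(theta_full)
    h = 1e-5 * np.maximum(1.0, np.abs(theta_full))
    hess = np.zeros((p, p))
    for j in range(p):
        tp, tm = theta_full.copy(), theta_full.copy()
        tp[j] += h[j]
        tm[j] -= h[j]
        hess[:, j] = (
            _score(tp, patterns, counts, k, anchor)
            - _score(tm, patterns, counts, k, anchor)
        ) / (2 * h[j])
    hess = 0.5 * (hess + hess.T)
    info = -hess
    try:
        cov = np.linalg.inv(info)
        var = np.diag(cov).copy()
    except np.linalg.LinAlgError:
        var = np.full(p, np.nan)
    var = np.where(var > 0, var, np.nan)
    se = np.sqrt(var)
    out = {
        "growth": se[: 5 * k].reshape(k, 5),
        "thresholds_free": se[5 * k : 5 * k + 2],
        "proportion_logits": se[5 * k + 2 :],
    }
    return out
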