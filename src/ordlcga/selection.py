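"""Class-enumeration statistics and the K-selection workflow.

For each candidate class count K the fit table reports the penalized
-2 log L criteria

    BIC  = -2 LL + p ln N
    CAIC = -2 LL + p (ln N + 1)
    AWE  = -2 LL + 2 p (ln N + 1.5)

with the nominal parameter count p = 6K + 2, an approximate Bayes factor for
K versus K+1 via the Schwarz information criterion SIC = -BIC/2, the
approximate correct-model probability cmP_A over a user-chosen candidate set,
and the relative entropy of the posterior classification.  All exponentials
are taken in log space so arbitrarily large BIC gaps never overflow.

Selection is advisory: the smallest-BIC model whose best log likelihood
replicated across starts is recommended, with elbow deltas reported so the
final call can blend fit, parsimony and interpretability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .em import MixtureFit, em_fit

__all__ = [
    "information_criteria",
    "approx_bayes_factor",
    "correct_model_probability",
    "relative_entropy",
    "enumerate_classes",
    "EnumerationResult",
]


def information_criteria(loglik: float, n_params: int, n_obs: int):
    """(BIC, CAIC, AWE) from a log likelihood, parameter count and N."""
    if n_obs < 2 or n_params < 0:
        raise ValueError("need n_obs >= 2 and n_params >= 0")
    if not np.isfinite(loglik):
        return (np.nan, np.nan, np.nan)
    ln_n = np.log(n_obs)
    bic = -2.0 * loglik + n_params * ln_n
    caic = -2.0 * loglik + n_params * (ln_n + 1.0)
    awe = -2.0 * loglik + 2.0 * n_params * (ln_n + 1.5)
    return (bic, caic, awe)


def approx_bayes_factor(bic_k: float, bic_k1: float) -> float:
    """Approximate Bayes factor for model k versus k+1, exp(SIC_k - SIC_k+1)
    with SIC = -BIC/2; underflows gracefully to 0.0 for huge BIC gaps."""
    log_bf = 0.5 * (bic_k1 - bic_k)
    if log_bf > 700:
        return np.inf
    return float(np.exp(log_bf))


def format_bayes_factor(bf: float) -> str:
    """Report style: values below .01 print as '<.01', above 100 as '>100'."""
    if not np.isfinite(bf):
        return ">100" if bf > 0 else "nan"
    if bf < 0.01:
        return "<.01"
    if bf > 100:
        return ">100"
    return f"{bf:.2f}"


def correct_model_probability(bics) -> np.ndarray:
    """cmP_A over a candidate set: softmax of SIC = -BIC/2, max-shifted so it
    never overflows.  Sums to 1."""
    bics = np.asarray(bics, dtype=float)
    if bics.size < 2:
        raise ValueError("cmP_A needs at least two candidate models")
    sic = -bics / 2.0
    shifted = sic - sic.max()
    w = np.exp(shifted)
    return w / w.sum()


def relative_entropy(posterior: np.ndarray) -> float:
    """Relative entropy E_K = 1 - sum_i sum_c (-p_ic ln p_ic) / (N ln K).

    1 means perfect classification, 0 means uniform posteriors.  Undefined
    for K = 1 (returns NaN).  Invariant to row order and class permutation.
    """
    p = np.asarray(posterior, dtype=float)
    n, k = p.shape
    if k < 2:
        return np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    return float(1.0 - terms.sum() / (n * np.log(k)))


@dataclass
class EnumerationResult:
    """Fit-statistic table plus the fits it was computed from."""

    table: pd.DataFrame
    fits: dict  # K -> MixtureFit
    recommended_k: int | None

    def candidate_cmp(self, ks) -> np.ndarray:
        """cmP_A restricted to a chosen candidate set of class counts."""
        bics = [self.table.set_index("K").loc[k, "BIC"] for k in ks]
        return correct_model_probability(bics)


def fit_stat_table(fits: dict[int, MixtureFit]) -> pd.DataFrame:
    """Assemble the enumeration table from fitted models keyed by K."""
    ks = sorted(fits)
    rows = []
    for k in ks:
        f = fits[k]
        bic, caic, awe = information_criteria(f.loglik, f.n_params, f.n_obs)
        rows.append(
            {
                "K": k,
                "n_params": f.n_params,
                "loglik": f.loglik,
                "BIC": bic,
                "CAIC": caic,
                "AWE": awe,
                "entropy": relative_entropy(f.posterior) if k >= 2 else np.nan,
                "converged": f.converged,
                "replicated": f.n_replicated >= 2,
            }
        )
    df = pd.DataFrame(rows)
    bf = [
        approx_bayes_factor(df.loc[i, "BIC"], df.loc[i + 1, "BIC"])
        for i in range(len(df) - 1)
    ] + [np.nan]
    df["BF_next"] = bf
    df["cmP_A"] = correct_model_probability(df["BIC"]) if len(df) >= 2 else np.nan
    for col in ("BIC", "CAIC", "AWE"):
        df[f"d{col}"] = df[col].diff()
    return df


def enumerate_classes(
    data,
    k_max: int,
    *,
    seed: int = 0,
    n_starts: int = 50,
    n_final: int = 20,
    warm_start: bool = True,
    **fit_kwargs,
) -> EnumerationResult:
    """Fit K = 1..k_max sequentially and assemble the fit-statistic table.

    Each K's fit reuses information from the previous solution: one extra
    start seeds EM from the (K-1)-class estimates with the largest class
    split, which is the practical warm-start that aids convergence at larger
    K.  Non-replicating or non-converged rows are flagged, never dropped.
    The recommendation is the smallest-BIC K among replicated solutions.
    """
    fits: dict[int, MixtureFit] = {}
    prev_fit = None
    for k in range(1, k_max + 1):
        fit = em_fit(
            data, k, n_starts=n_starts, n_final=n_final,
            seed=seed + 1000 * k, **fit_kwargs,
        )
        if warm_start and prev_fit is not None:
            warm = _split_largest(prev_fit, data, seed=seed + 1000 * k + 1, **fit_kwargs)
            if warm is not None and warm.loglik > fit.loglik + 1e-9:
                warm.n_starts = fit.n_starts + 1
                warm.n_replicated = max(
                    warm.n_replicated,
                    sum(1 for x in fit.start_logliks if abs(x - warm.loglik) < 1e-2) + 1,
                )
                fit = warm
        fits[k] = fit
        prev_fit = fit
    table = fit_stat_table(fits)
    ok = table[table["replicated"] & table["converged"]]
    rec = int(ok.loc[ok["BIC"].idxmin(), "K"]) if len(ok) else None
    return EnumerationResult(table=table, fits=fits, recommended_k=rec)


def _split_largest(prev: MixtureFit, data, seed: int, **fit_kwargs):
    """EM run seeded by splitting the previous fit's largest class in two."""
    from .em import _pack, _run_em, _spec_from_theta
    from .model import _as_category_matrix, posterior as _posterior
    from .em import order_classes

    spec = prev.spec
    k_new = spec.n_classes + 1
    rng = np.random.default_rng(seed)
    j = int(np.argmax(spec.weights))
    classes = [c for c in spec.classes]
    import copy

    twin = copy.deepcopy(classes[j])
    twin.intercept += rng.normal(0, 0.5)
    twin.slope += rng.normal(0, 0.5)
    classes.append(twin)
    w = spec.weights.copy()
    w_j = w[j]
    w[j] = w_j / 2
    w = np.r_[w, w_j / 2]
    try:
        spec0 = type(spec)(w, classes, spec.thresholds.copy(), anchor=spec.anchor)
    except ValueError:
        return None
    y = _as_category_matrix(data)
    patterns, counts = np.unique(y, axis=0, return_counts=True)
    tol = fit_kwargs.get("tol", 1e-8)
    max_iter = fit_kwargs.get("max_iter", 500)
    theta, pi, ll, conv, _ = _run_em(patterns, counts.astype(float), spec0, tol, max_iter)
    if np.any(pi < 0.5 / len(y)):
        return None
    fit = MixtureFit(
        spec=_spec_from_theta(theta, pi, k_new, spec.anchor),
        loglik=ll,
        posterior=np.empty((0, k_new)),
        n_obs=len(y),
        converged=conv,
        seed=seed,
        n_starts=1,
        n_replicated=1,
    )
    fit = order_classes(fit)
    fit.posterior = _posterior(y, fit.spec)
    return fit
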