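"""Ordinal latent-class growth model.

The observed outcome is a 4-category ordinal severity rating at up to five
discretized waves.  Within class ``c`` the latent response at wave ``t`` is a
deterministic free-loading growth curve

    eta_ct = alpha_c + beta_c * lambda_t,      lambda_1 = 0, lambda_5 = 1,

and the observed category arises by cutting a standard-logistic deviation
around ``eta_ct`` at three thresholds ``tau`` shared across classes and waves
(an ordered-logit / proportional-odds measurement model).  Within-class growth
variances are fixed at zero, so waves are conditionally independent given
class and missing waves simply drop out of the likelihood (MAR).

Because intercepts and thresholds are jointly free, the likelihood is
invariant to a common additive shift of all ``alpha_c`` and ``tau_k``; the
model is identified by anchoring ``tau_2`` at a fixed value (see
:class:`MixtureSpec.anchor`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_expit, logsumexp

N_WAVES = 5
N_CATS = 4

__all__ = [
    "ClassGrowthParams",
    "MixtureSpec",
    "linear_predictor",
    "category_probs",
    "ordered_logit_logprobs",
    "log_prob_table",
    "person_loglik_by_class",
    "mixture_loglik",
    "posterior",
]


@dataclass
class ClassGrowthParams:
    """Growth-curve parameters for one trajectory class.

    Parameters are on the latent-response (logit) scale.  ``loadings`` is the
    5-vector of time scores; its endpoints are fixed at 0 and 1 so the slope
    is the total baseline-to-endpoint change and interior loadings locate the
    curve between the endpoints (values outside [0, 1] produce non-monotone
    shapes).
    """

    intercept: float
    slope: float
    loadings: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.25, 0.5, 0.75, 1.0])
    )

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        if self.loadings.shape != (N_WAVES,):
            raise ValueError(f"loadings must have length {N_WAVES}")
        if self.loadings[0] != 0.0 or self.loadings[-1] != 1.0:
            raise ValueError("loadings must be fixed at 0 (baseline) and 1 (endpoint)")

    @property
    def eta(self) -> np.ndarray:
        """Linear predictor at all five waves."""
        return self.intercept + self.slope * self.loadings


@dataclass
class MixtureSpec:
    """A K-class ordinal growth mixture.

    Attributes
    ----------
    weights : (K,) class proportions, positive, summing to 1.
    classes : K :class:`ClassGrowthParams`.
    thresholds : (3,) strictly increasing ordered-logit cut points, shared
        across classes and waves.
    anchor : the fixed value of ``thresholds[1]`` used for identification
        during estimation.  Reparameterizing to another anchor is an additive
        shift of every intercept and threshold and leaves the likelihood
        unchanged.
    """

    weights: np.ndarray
    classes: list[ClassGrowthParams]
    thresholds: np.ndarray
    anchor: float = 0.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.validate()

    def validate(self) -> None:
        if len(self.classes) != len(self.weights):
            raise ValueError("weights and classes length mismatch")
        if np.any(self.weights <= 0) or abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("class proportions must be positive and sum to 1")
        if self.thresholds.shape != (N_CATS - 1,):
            raise ValueError("exactly 3 thresholds required for 4 categories")
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def n_params(self) -> int:
        """Nominal free-parameter count 6K + 2.

        Per class: intercept, slope and three free loadings; plus three
        thresholds and K-1 free proportions.  This is the conventional count
        used in information criteria; it ignores the location anchor.
        """
        k = self.n_classes
        return 6 * k + 2

    def eta_matrix(self) -> np.ndarray:
        """(K, 5) linear predictors."""
        return np.stack([c.eta for c in self.classes])

    def shifted(self, new_anchor: float) -> "MixtureSpec":
        """Re-express all location parameters in another threshold anchor."""
        delta = new_anchor - self.thresholds[1]
        classes = [
            ClassGrowthParams(c.intercept + delta, c.slope, c.loadings.copy())
            for c in self.classes
        ]
        return MixtureSpec(
            self.weights.copy(), classes, self.thresholds + delta, anchor=new_anchor
        )

    # -- serialization (layout mirrors the per-class parameter table) --------

    def to_dict(self) -> dict:
        return {
            "anchor": float(self.anchor),
            "proportions": [float(w) for w in self.weights],
            "classes": [
                {
                    "intercept": float(c.intercept),
                    "slope": float(c.slope),
                    "loadings": [float(x) for x in c.loadings],
                }
                for c in self.classes
            ],
            "thresholds": [float(t) for t in self.thresholds],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureSpec":
        classes = [
            ClassGrowthParams(c["intercept"], c["slope"], np.asarray(c["loadings"]))
            for c in d["classes"]
        ]
        return cls(
            np.asarray(d["proportions"], dtype=float),
            classes,
            np.asarray(d["thresholds"], dtype=float),
            anchor=float(d.get("anchor", 0.0)),
        )


def linear_predictor(params: ClassGrowthParams, wave: int) -> float:
    """eta at a 1-based wave index."""
    if not 1 <= wave <= N_WAVES:
        raise ValueError("wave must be in 1..5")
    return float(params.intercept + params.slope * params.loadings[wave - 1])


def ordered_logit_logprobs(eta, tau) -> np.ndarray:
    """Log category probabilities of the ordered-logit measurement model.

    Stable for arbitrarily extreme ``eta``: interior categories use
    ``log(sigma(b) - sigma(a)) = log_expit(b) + log_expit(-a) + log1p(-exp(a-b))``
    which never subtracts nearly-equal probabilities.

    Parameters
    ----------
    eta : array-like, any shape S.
    tau : (3,) strictly increasing thresholds.

    Returns
    -------
    (S..., 4) array of log probabilities summing to 1 across the last axis.
    """
    eta = np.asarray(eta, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if tau.shape != (N_CATS - 1,) or np.any(np.diff(tau) <= 0):
        raise ValueError("thresholds must be a strictly increasing 3-vector")
    out = np.empty(eta.shape + (N_CATS,))
    out[..., 0] = log_expit(tau[0] - eta)
    for k in (1, 2):
        a = tau[k - 1] - eta
        b = tau[k] - eta
        out[..., k] = log_expit(b) + log_expit(-a) + np.log1p(-np.exp(tau[k - 1] - tau[k]))
    out[..., 3] = log_expit(eta - tau[2])
    return out


def category_probs(eta, tau) -> np.ndarray:
    """Category probabilities P(Y = 1..4 | eta, tau); sums to 1."""
    return np.exp(ordered_logit_logprobs(eta, tau))


def log_prob_table(spec: MixtureSpec) -> np.ndarray:
    """(K, 5, 4) table of log P(Y_t = k | class c) under ``spec``."""
    return ordered_logit_logprobs(spec.eta_matrix(), spec.thresholds)


def _as_category_matrix(data) -> np.ndarray:
    """Coerce input to an (N, 5) int matrix; 0 marks a missing wave."""
    y = np.asarray(data)
    if y.ndim == 1:
        y = y[None, :]
    if y.shape[1] != N_WAVES:
        raise ValueError(f"expected {N_WAVES} wave columns")
    if np.issubdtype(y.dtype, np.floating):
        y = np.where(np.isnan(y), 0, y).astype(int)
    y = y.astype(int)
    if y.min() < 0 or y.max() > N_CATS:
        raise ValueError("categories must lie in 1..4 (0/NaN = missing)")
    return y


def person_loglik_by_class(data, spec: MixtureSpec) -> np.ndarray:
    """(N, K) log conditional likelihoods log P(y_i | class c).

    ``data`` is an (N, 5) category matrix with 0/NaN marking missing waves;
    missing waves contribute nothing (their categories are marginalized out
    analytically because the four category probabilities sum to one).
    """
    y = _as_category_matrix(data)
    table = log_prob_table(spec)  # K x 5 x 4
    n, k = y.shape[0], spec.n_classes
    out = np.zeros((n, k))
    for t in range(N_WAVES):
        obs = y[:, t] > 0
        if not obs.any():
            continue
        out[obs] += table[:, t, y[obs, t] - 1].T
    return out


def mixture_loglik(data, spec: MixtureSpec, weights=None) -> float:
    """Observed-data mixture log likelihood, computed with log-sum-exp.

    ``weights`` optionally gives per-row multiplicities (for pattern-collapsed
    data).
    """
    ll_ic = person_loglik_by_class(data, spec)
    per_person = logsumexp(ll_ic + np.log(spec.weights), axis=1)
    if weights is None:
        return float(per_person.sum())
    return float(np.dot(np.asarray(weights, dtype=float), per_person))


def posterior(data, spec: MixtureSpec) -> np.ndarray:
    """(N, K) posterior class-membership probabilities; rows sum to 1."""
    ll_ic = person_loglik_by_class(data, spec) + np.log(spec.weights)
    norm = logsumexp(ll_ic, axis=1, keepdims=True)
    return np.exp(ll_ic - norm)
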