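"""Synthetic cohort generator.

Emulates the statistical structure the pipeline assumes: participants are
drawn from latent trajectory classes; each class's 4-category ordinal
severity sequence arises by cutting a logistic deviation around its growth
curve at the shared thresholds; baseline covariates and a continuous distal
outcome are drawn class-conditionally; and a missingness engine reproduces
the sparse assessment patterns of the motivating cohort (mean ~2.10
assessments, ~9% of participants at 3+ waves, late waves most commonly
observed).  Covariates are independent within class — published tables give
marginals only — which the methods note records as a limitation.

Everything is deterministic given a seed, and each participant has an
independent substream, so growing N extends the cohort without reordering
the participants already generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import reference as ref
from .model import MixtureSpec, N_WAVES
from .preprocess import DAYS_PER_MONTH, WAVE_EDGES_MONTHS

__all__ = [
    "CohortConfig",
    "default_study_config",
    "generate_cohort",
    "missingness_engine",
    "calibrate_assessment_counts",
]

#: integer day ranges (inclusive) for waves 2-5, consistent with the
#: lower-exclusive / upper-inclusive month windows at 30.44 days per month
_WAVE_DAY_RANGES = [
    (int(np.floor(lo * DAYS_PER_MONTH)) + 1, int(np.floor(hi * DAYS_PER_MONTH)))
    for lo, hi in WAVE_EDGES_MONTHS
]
#: score bands per severity category (uniform within band when emitting a
#: 0-10 score consistent with a generated category)
_SCORE_BANDS = {1: (0, 1), 2: (2, 3), 3: (4, 6), 4: (7, 10)}


@dataclass
class CohortConfig:
    """Everything needed to generate a cohort; defaults mirror the published
    study scenario (see :func:`default_study_config`)."""

    n: int
    spec: MixtureSpec
    class_names: list[str]
    continuous: dict  # name -> {"sd": float, "by_class": [K means]}
    binary: dict      # name -> [K probabilities]
    categorical: dict  # name -> {level: [K probabilities]}
    distal_means: list
    distal_sd: float
    mean_assessments: float = ref.MEAN_ASSESSMENTS
    p_three_plus: float = ref.P_THREE_PLUS
    wave_propensities: np.ndarray = field(
        default_factory=lambda: ref.WAVE_PROPENSITIES.copy()
    )
    missingness_tilt: dict | None = None
    apply_missingness: bool = True

    def __post_init__(self) -> None:
        self.wave_propensities = np.asarray(self.wave_propensities, dtype=float)
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if len(self.class_names) != self.spec.n_classes:
            raise ValueError("class_names must match the number of classes")
        if self.wave_propensities.shape != (4,) or (self.wave_propensities < 0).any() \
                or self.wave_propensities.sum() <= 0:
            raise ValueError("wave_propensities must be 4 non-negative weights")
        for name, levels in self.categorical.items():
            probs = np.asarray(list(levels.values()), dtype=float)
            # published category percentages can leave a small remainder
            # (differing denominators); they are renormalized when sampled
            if np.any(probs < 0) or np.any(np.abs(probs.sum(axis=0) - 1.0) > 0.05):
                raise ValueError(f"categorical probabilities for {name!r} invalid")
        for name, p in self.binary.items():
            p = np.asarray(p, dtype=float)
            if np.any((p < 0) | (p > 1)):
                raise ValueError(f"binary probabilities for {name!r} invalid")

    def to_dict(self) -> dict:
        return {
            "n": int(self.n),
            "spec": self.spec.to_dict(),
            "class_names": list(self.class_names),
            "continuous": {k: {"sd": float(v["sd"]),
                               "by_class": [float(x) for x in v["by_class"]]}
                           for k, v in self.continuous.items()},
            "binary": {k: [float(x) for x in v] for k, v in self.binary.items()},
            "categorical": {k: {lv: [float(x) for x in p] for lv, p in v.items()}
                            for k, v in self.categorical.items()},
            "distal_means": [float(x) for x in self.distal_means],
            "distal_sd": float(self.distal_sd),
            "mean_assessments": float(self.mean_assessments),
            "p_three_plus": float(self.p_three_plus),
            "wave_propensities": [float(x) for x in self.wave_propensities],
            "missingness_tilt": dict(self.missingness_tilt) if self.missingness_tilt else None,
            "apply_missingness": bool(self.apply_missingness),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        d["spec"] = MixtureSpec.from_dict(d["spec"])
        d["wave_propensities"] = np.asarray(d["wave_propensities"], dtype=float)
        return cls(**d)


def default_study_config(n: int = 10_000, *, apply_missingness: bool = True) -> CohortConfig:
    """The default study scenario: published growth parameters and class
    proportions, class-conditional covariates from the published descriptive
    tables, the implied distal-outcome means, and the calibrated sparse
    missingness design.  Numeric origins are listed in
    :data:`ordlcga.reference.PROVENANCE`."""
    spec = ref.published_spec()
    means = ref.wpai_class_means()
    return CohortConfig(
        n=n,
        spec=spec,
        class_names=list(ref.CLASS_NAMES),
        continuous={
            name: {"sd": info["full"][1], "by_class": list(info["by_class"])}
            for name, info in ref.CONTINUOUS_COVARIATES.items()
        },
        binary={k: list(v) for k, v in ref.BINARY_COVARIATES.items()},
        categorical={k: {lv: list(p) for lv, p in v.items()}
                     for k, v in ref.CATEGORICAL_COVARIATES.items()},
        distal_means=[means[c] for c in ref.CLASS_NAMES],
        distal_sd=ref.WPAI_POOLED_SD,
        apply_missingness=apply_missingness,
    )


def calibrate_assessment_counts(mean_total: float, p_three_plus: float) -> np.ndarray:
    """Distribution of post-baseline assessment counts A in {1, 2, 3, 4}.

    P(A = 1) comes straight from the 3+-wave target (total waves = 1 + A);
    the tail over {2, 3, 4} is a truncated geometric whose ratio is solved so
    the mean total assessment count matches ``mean_total``.
    """
    if not 0 < p_three_plus < 1:
        raise ValueError("p_three_plus must be in (0, 1)")
    p1 = 1.0 - p_three_plus
    target_tail_mean = (mean_total - 1.0 - p1) / p_three_plus  # E[A | A >= 2]
    if not 2.0 < target_tail_mean < 4.0:
        raise ValueError("targets are jointly infeasible for a {2,3,4} tail")

    def tail_mean(r):
        w = np.array([1.0, r, r * r])
        return float(np.dot([2, 3, 4], w) / w.sum())

    r = brentq(lambda r: tail_mean(r) - target_tail_mean, 1e-12, 1e6)
    tail = np.array([1.0, r, r * r])
    tail = p_three_plus * tail / tail.sum()
    return np.r_[p1, tail]


def missingness_engine(
    rng: np.random.Generator,
    count_probs: np.ndarray,
    wave_propensities: np.ndarray,
    tilt_shift: float = 0.0,
) -> list[int]:
    """Retained wave subset for one participant (1-based; baseline always).

    ``count_probs`` is the calibrated distribution of post-baseline counts;
    ``tilt_shift`` adds a logit shift to the probability of 3+ total waves
    (used to plant covariate-linked missingness for recovery tests).  Wave
    placement is weighted sampling without replacement by propensity (Gumbel
    top-k), so zero-propensity waves are never chosen.
    """
    p3 = 1.0 - count_probs[0]
    if tilt_shift != 0.0:
        p3 = 1.0 / (1.0 + np.exp(-(np.log(p3 / (1 - p3)) + tilt_shift)))
    if rng.random() < 1.0 - p3:
        a = 1
    else:
        tail = count_probs[1:] / count_probs[1:].sum()
        a = 2 + int(rng.choice(3, p=tail))
    pos = wave_propensities > 0
    a = min(a, int(pos.sum()))
    with np.errstate(divide="ignore"):
        keys = np.where(pos, np.log(wave_propensities) + rng.gumbel(size=4), -np.inf)
    chosen = np.argsort(-keys)[:a]
    return [1] + sorted(int(w) + 2 for w in chosen)


def generate_cohort(config: CohortConfig, seed: int):
    """Generate a cohort; returns ``(long_df, truth_df)``.

    ``long_df`` is the long-format assessment table (one row per completed
    assessment: participant id, day offset, 0-10 score, baseline covariates,
    distal outcome).  ``truth_df`` holds per-participant generating truth:
    class, the complete 5-wave category sequence (``y1..y5``) and the
    retained-wave mask — the oracle for recovery tests.
    """
    spec = config.spec
    k = spec.n_classes
    eta = spec.eta_matrix()
    tau = spec.thresholds
    cum_pi = np.cumsum(spec.weights)
    count_probs = calibrate_assessment_counts(config.mean_assessments,
                                              config.p_three_plus)
    tilt = config.missingness_tilt or {}

    children = np.random.SeedSequence(seed).spawn(config.n)
    long_rows, truth_rows = [], []
    for j in range(config.n):
        rng = np.random.default_rng(children[j])
        pid = f"p{j:06d}"
        c = int(np.searchsorted(cum_pi, rng.random(), side="right"))
        c = min(c, k - 1)
        latent = eta[c] + rng.logistic(size=N_WAVES)
        cats = 1 + (latent[:, None] > tau[None, :]).sum(axis=1)

        covs = {}
        # sorted iteration: the draw sequence (and so the output) does not
        # depend on dict insertion order, e.g. after a YAML round trip
        for name in sorted(config.continuous):
            info = config.continuous[name]
            covs[name] = float(info["by_class"][c] + info["sd"] * rng.normal())
        for name in sorted(config.binary):
            covs[name] = int(rng.random() < config.binary[name][c])
        for name in sorted(config.categorical):
            levels = config.categorical[name]
            names = sorted(levels)
            probs = np.array([levels[lv][c] for lv in names])
            covs[name] = names[int(rng.choice(len(names), p=probs / probs.sum()))]
        wpai = float(config.distal_means[c] + config.distal_sd * rng.normal())

        if config.apply_missingness:
            shift = sum(coef * covs.get(name, 0.0) for name, coef in tilt.items())
            waves = missingness_engine(rng, count_probs,
                                       config.wave_propensities, shift)
        else:
            waves = list(range(1, N_WAVES + 1))

        for w in waves:
            if w == 1:
                day = 0
            else:
                lo, hi = _WAVE_DAY_RANGES[w - 2]
                day = int(rng.integers(lo, hi + 1))
            lo_s, hi_s = _SCORE_BANDS[int(cats[w - 1])]
            score = int(rng.integers(lo_s, hi_s + 1))
            row = {"participant_id": pid, "day_offset": day, "cesd_score": score}
            row.update(covs)
            row["wpai_total"] = wpai
            long_rows.append(row)

        truth = {"participant_id": pid, "true_class": c,
                 "class_name": config.class_names[c]}
        truth.update({f"y{t + 1}": int(cats[t]) for t in range(N_WAVES)})
        truth.update({f"obs{t + 1}": int(t + 1 in waves) for t in range(N_WAVES)})
        truth["n_assessments"] = len(waves)
        truth["wpai_total"] = wpai
        truth_rows.append(truth)

    long_df = pd.DataFrame(long_rows).sort_values(
        ["participant_id", "day_offset"], kind="stable", ignore_index=True
    )
    truth_df = pd.DataFrame(truth_rows)
    return long_df, truth_df
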