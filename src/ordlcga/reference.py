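"""Published estimates from the motivating web-based HRA depression-trajectory
study (N = 22,963), used as the default generative scenario and for analytic
identity checks.

Five trajectory classes of 4-category ordinal depressive severity over five
waves (baseline, 0.5-3, 3-6, 6-9, 9-15 months): minimal, low-risk,
deteriorating, remitting and chronic.  Values are transcribed from the
published class-parameter, fit-statistic, covariate-descriptive and
predictor tables; each constant's origin is recorded in :data:`PROVENANCE`.
"""

from __future__ import annotations

import numpy as np

from .model import ClassGrowthParams, MixtureSpec

N_PUBLISHED = 22_963

CLASS_NAMES = ["minimal", "low_risk", "deteriorating", "remitting", "chronic"]

#: model-estimated class proportions (%); they print to a 100.01% total and
#: are renormalized before use (the renormalization is logged in PROVENANCE)
CLASS_PROPORTIONS_PCT = {
    "minimal": 63.66,
    "low_risk": 18.65,
    "deteriorating": 4.69,
    "remitting": 8.05,
    "chronic": 4.96,
}

#: modal-assignment class counts (denominator N_PUBLISHED)
MODAL_COUNTS = {
    "minimal": 14_676,
    "low_risk": 4_568,
    "deteriorating": 705,
    "remitting": 1_933,
    "chronic": 1_081,
}

#: growth parameters on the published latent-response scale
GROWTH = {
    "minimal": {"intercept": -51.05, "slope": 6.12,
                "loadings": [0.00, -14.61, -16.52, 0.73, 1.00]},
    "low_risk": {"intercept": -38.14, "slope": -5.14,
                 "loadings": [0.00, 0.36, 0.26, 0.70, 1.00]},
    "deteriorating": {"intercept": -42.31, "slope": 12.56,
                      "loadings": [0.00, 0.35, 0.09, 0.54, 1.00]},
    "remitting": {"intercept": -30.35, "slope": -12.63,
                  "loadings": [0.00, 0.07, 0.08, 0.18, 1.00]},
    "chronic": {"intercept": -27.64, "slope": -0.98,
                "loadings": [0.00, -1.51, -1.24, -1.17, 1.00]},
}

#: thresholds shared across classes and waves; the middle one is the
#: conventional anchor when reproducing the published parameterization
THRESHOLDS = np.array([-43.01, -35.02, -27.90])
PUBLISHED_ANCHOR = -35.02

#: published enumeration table: K -> (n_params, loglik, BIC, CAIC, AWE)
FIT_STATS = {
    1: (8, -36_256, 72_593, 72_601, 72_697),
    2: (14, -37_384, 74_909, 74_923, 75_092),
    3: (20, -35_123, 70_448, 70_468, 70_709),
    4: (26, -34_386, 69_033, 69_059, 69_372),
    5: (32, -33_424, 67_170, 67_202, 67_587),
    6: (38, -32_975, 66_332, 66_370, 66_828),
}
ENTROPY_5CLASS = 0.95

#: continuous covariates: full-sample (mean, sd) and per-class means.
#: Within-class SDs are not published; the generator reuses the full-sample
#: SD within class (a documented, slightly overdispersed choice).
CONTINUOUS_COVARIATES = {
    "age": {"full": (45.84, 11.72),
            "by_class": [47.09, 44.22, 41.43, 43.72, 42.44]},
    "life_quality": {"full": (2.87, 0.79),
                     "by_class": [3.04, 2.69, 2.72, 2.40, 2.09]},
    "health_quality": {"full": (2.63, 0.83),
                       "by_class": [2.81, 2.45, 2.47, 2.17, 1.92]},
    "sleep_quality": {"full": (6.80, 2.14),
                      "by_class": [7.44, 5.98, 6.29, 5.24, 4.61]},
    "sleep_hours": {"full": (7.07, 1.21),
                    "by_class": [7.24, 6.84, 6.94, 6.67, 6.51]},
    "stress": {"full": (4.04, 1.06),
               "by_class": [3.92, 4.12, 4.14, 4.40, 4.61]},
    "alcohol": {"full": (9.50, 1.34),
                "by_class": [9.60, 9.39, 9.35, 9.21, 9.16]},
}

#: binary covariates: per-class probabilities (class order = CLASS_NAMES).
#: physical_activity prints as mean 0.88 / SD 0.32 in the continuous table,
#: i.e. a 0/1 code; it is generated as Bernoulli.
BINARY_COVARIATES = {
    "physical_activity": [0.91, 0.86, 0.89, 0.81, 0.80],
    "female": [0.6339, 0.7012, 0.7490, 0.7685, 0.7905],
    "treatment": [0.0457, 0.1101, 0.1630, 0.1976, 0.3682],
    "pregnant": [0.0124, 0.0169, 0.0100, 0.0145, 0.0111],
    "lives_alone": [0.1160, 0.1322, 0.1360, 0.1526, 0.1536],
    "child_0_2": [0.0622, 0.0760, 0.0970, 0.0688, 0.0611],
    "child_2_12": [0.2475, 0.2826, 0.3600, 0.2990, 0.3265],
    "child_12_18": [0.1934, 0.2220, 0.2450, 0.2023, 0.2313],
    "lives_adult": [0.7649, 0.7266, 0.7050, 0.6999, 0.6790],
}

#: categorical covariates: level -> per-class probabilities
CATEGORICAL_COVARIATES = {
    "relationship": {
        "single": [0.1076, 0.1490, 0.1460, 0.1719, 0.1702],
        "dating": [0.0478, 0.0629, 0.0860, 0.0643, 0.0659],
        "married": [0.6845, 0.5974, 0.5940, 0.5574, 0.5444],
        "divorced": [0.1302, 0.1524, 0.1530, 0.1657, 0.1903],
        "widowed": [0.0178, 0.0217, 0.0110, 0.0265, 0.0183],
    },
    "weight_category": {
        "healthy": [0.3545, 0.3161, 0.3020, 0.2706, 0.2507],
        "overweight": [0.3378, 0.3058, 0.2870, 0.2985, 0.2553],
        "obese": [0.2578, 0.2993, 0.3120, 0.3207, 0.3728],
        "extremely_obese": [0.0499, 0.0788, 0.0990, 0.1102, 0.1212],
    },
}

#: final prediction model, log odds / odds ratios vs the minimal class, plus
#: the published focal contrasts; (class, predictor, log_odds, odds_ratio)
PREDICTOR_TABLE = [
    ("low_risk", "age", -0.03, 0.97), ("low_risk", "male", -0.23, 0.79),
    ("low_risk", "sleep_quality", -0.67, 0.51), ("low_risk", "sleep_hours", -0.10, 0.91),
    ("low_risk", "stress", 0.20, 1.22), ("low_risk", "life_quality", -0.31, 0.73),
    ("low_risk", "health_quality", -0.13, 0.88), ("low_risk", "treatment", 0.72, 2.06),
    ("deteriorating", "age", -0.05, 0.95), ("deteriorating", "male", -0.49, 0.61),
    ("deteriorating", "sleep_quality", -0.51, 0.60), ("deteriorating", "sleep_hours", -0.09, 0.92),
    ("deteriorating", "stress", 0.22, 1.25), ("deteriorating", "life_quality", -0.30, 0.74),
    ("deteriorating", "health_quality", -0.15, 0.86), ("deteriorating", "treatment", 1.29, 3.64),
    ("remitting", "age", -0.04, 0.96), ("remitting", "male", -0.55, 0.58),
    ("remitting", "sleep_quality", -0.90, 0.41), ("remitting", "sleep_hours", -0.12, 0.88),
    ("remitting", "stress", 0.43, 1.53), ("remitting", "life_quality", -0.57, 0.57),
    ("remitting", "health_quality", -0.28, 0.76), ("remitting", "treatment", 1.32, 3.73),
    ("chronic", "age", -0.06, 0.94), ("chronic", "male", -0.58, 0.56),
    ("chronic", "sleep_quality", -1.12, 0.33), ("chronic", "sleep_hours", -0.14, 0.87),
    ("chronic", "stress", 0.55, 1.73), ("chronic", "life_quality", -0.94, 0.39),
    ("chronic", "health_quality", -0.30, 0.74), ("chronic", "treatment", 2.14, 8.49),
]

CONTRAST_TABLE = [
    ("deteriorating", "low_risk", "age", -0.02, 0.98),
    ("deteriorating", "low_risk", "male", -0.26, 0.77),
    ("deteriorating", "low_risk", "sleep_quality", 0.16, 1.17),
    ("deteriorating", "low_risk", "sleep_hours", 0.01, 1.01),
    ("deteriorating", "low_risk", "stress", 0.03, 1.03),
    ("deteriorating", "low_risk", "life_quality", 0.01, 1.01),
    ("deteriorating", "low_risk", "health_quality", -0.02, 0.98),
    ("deteriorating", "low_risk", "treatment", 0.57, 1.77),
    ("chronic", "remitting", "age", -0.02, 0.98),
    ("chronic", "remitting", "male", -0.03, 0.97),
    ("chronic", "remitting", "sleep_quality", -0.22, 0.81),
    ("chronic", "remitting", "sleep_hours", -0.02, 0.98),
    ("chronic", "remitting", "stress", 0.12, 1.13),
    ("chronic", "remitting", "life_quality", -0.67, 0.69),
    ("chronic", "remitting", "health_quality", -0.03, 0.97),
    ("chronic", "remitting", "treatment", 0.82, 2.28),
]

#: distal productivity-impairment outcome: published end-of-study mean
#: differences vs minimal and the three published effect sizes
WPAI_MDIFF_VS_MINIMAL = {
    "low_risk": 1.98, "deteriorating": 57.25, "remitting": 3.59, "chronic": 12.70,
}
WPAI_COHEN_D = {
    ("deteriorating", "low_risk"): 3.37,
    ("chronic", "remitting"): 0.55,
    ("deteriorating", "chronic"): 2.72,
}
#: the three published d values and their Mdiffs jointly imply a pooled
#: within-class SD of ~16.4 (55.26/3.37, 9.11/0.55, 44.55/2.72)
WPAI_POOLED_SD = 16.4
#: the minimal class's mean impairment is not published; a typical low value
#: on the 0-100 scale is assumed for generation
WPAI_MINIMAL_MEAN = 5.0

#: missingness design: total assessments average 2.10, 9% of participants
#: reach 3+ waves, and post-baseline response rates range from 16.45%
#: (6-9 months) to 46.00% (9-15 months); waves 2-3 are interpolated so the
#: marginals sum to the calibrated mean of 1.10 post-baseline assessments
MEAN_ASSESSMENTS = 2.10
P_THREE_PLUS = 0.09
WAVE_PROPENSITIES = np.array([0.2655, 0.21, 0.1645, 0.46])

PROVENANCE = {
    "CLASS_PROPORTIONS_PCT": "published class-parameter table header (model-estimated); "
                             "prints to 100.01% and is renormalized before sampling",
    "MODAL_COUNTS": "published covariate-descriptive tables (modal assignment)",
    "GROWTH": "published class-parameter table (intercepts, slopes, free loadings; "
              "baseline/endpoint loadings fixed at 0/1)",
    "THRESHOLDS": "published class-parameter table (constrained constant across classes)",
    "FIT_STATS": "published enumeration table (integer-rounded loglikelihoods)",
    "CONTINUOUS_COVARIATES": "published continuous-covariate table "
                             "(class means; full-sample SD reused within class)",
    "BINARY_COVARIATES": "published categorical-covariate table; physical activity "
                         "re-coded from its 0/1 continuous summary",
    "CATEGORICAL_COVARIATES": "published categorical-covariate table",
    "PREDICTOR_TABLE": "published final prediction model (minimal reference)",
    "CONTRAST_TABLE": "published focal contrasts",
    "WPAI": "published distal mean differences and effect sizes; pooled SD 16.4 "
            "implied, minimal-class mean 5.0 assumed",
    "MISSINGNESS": "published assessment-count summary (mean 2.10, 9% with 3+ waves) "
                   "and post-baseline response range; waves 2-3 interpolated",
}


def published_spec() -> MixtureSpec:
    """The published 5-class parameterization as a :class:`MixtureSpec`
    (anchored at the published middle threshold)."""
    pct = np.array([CLASS_PROPORTIONS_PCT[c] for c in CLASS_NAMES])
    weights = pct / pct.sum()
    classes = [
        ClassGrowthParams(GROWTH[c]["intercept"], GROWTH[c]["slope"],
                          np.asarray(GROWTH[c]["loadings"]))
        for c in CLASS_NAMES
    ]
    return MixtureSpec(weights, classes, THRESHOLDS.copy(), anchor=PUBLISHED_ANCHOR)


def wpai_class_means() -> dict:
    """Generative distal means implied by the published mean differences."""
    means = {"minimal": WPAI_MINIMAL_MEAN}
    for c, d in WPAI_MDIFF_VS_MINIMAL.items():
        means[c] = WPAI_MINIMAL_MEAN + d
    return means
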