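import numpy as np
import pytest

from ordlcga import ClassGrowthParams, MixtureSpec, generate_cohort, default_study_config


@pytest.fixture(scope="session")
def two_class_spec():
    """A well-separated 2-class spec on a moderate latent scale."""
    classes = [
        ClassGrowthParams(-2.5, 1.5, np.array([0.0, 0.3, 0.5, 0.8, 1.0])),
        ClassGrowthParams(1.8, -1.2, np.array([0.0, 0.2, 0.4, 0.7, 1.0])),
    ]
    return MixtureSpec(np.array([0.6, 0.4]), classes, np.array([-2.0, 0.0, 2.0]))


@pytest.fixture(scope="session")
def two_class_data(two_class_spec):
    """Complete 5-wave categories simulated from the 2-class spec."""
    rng = np.random.default_rng(42)
    n = 2000
    eta = two_class_spec.eta_matrix()
    cls = (rng.random(n) < two_class_spec.weights[1]).astype(int)
    latent = eta[cls] + rng.logistic(size=(n, 5))
    y = 1 + (latent[:, :, None] > two_class_spec.thresholds[None, None, :]).sum(axis=2)
    return y, cls


@pytest.fixture(scope="session")
def small_cohort():
    """A small sparse cohort from the default scenario (with missingness)."""
    cfg = default_study_config(400)
    return generate_cohort(cfg, seed=7)


@pytest.fixture(scope="session")
def small_complete_cohort():
    cfg = default_study_config(500, apply_missingness=False)
    return generate_cohort(cfg, seed=9)
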