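"""Synthetic cohort generator: calibration, determinism, round-trips."""

import numpy as np
import pandas as pd
import pytest
import yaml

from ordlcga import (
    CohortConfig,
    build_cohort,
    calibrate_assessment_counts,
    category_probs,
    generate_cohort,
    missingness_engine,
    default_study_config,
)
from ordlcga.reference import CLASS_NAMES, PROVENANCE


class TestCalibration:
    def test_targets_hit_exactly(self):
        probs = calibrate_assessment_counts(2.10, 0.09)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert 1.0 + np.dot(probs, [1, 2, 3, 4]) == pytest.approx(2.10, abs=1e-10)
        assert probs[1:].sum() == pytest.approx(0.09, abs=1e-12)

    def test_infeasible_targets_rejected(self):
        with pytest.raises(ValueError):
            calibrate_assessment_counts(5.5, 0.09)
        with pytest.raises(ValueError):
            calibrate_assessment_counts(2.1, 0.0)


class TestMissingnessEngine:
    def test_all_mass_on_last_wave(self):
        probs = calibrate_assessment_counts(2.10, 0.09)
        rng = np.random.default_rng(0)
        for _ in range(50):
            waves = missingness_engine(rng, probs, np.array([0.0, 0.0, 0.0, 1.0]))
            assert waves == [1, 5]

    def test_baseline_always_present(self):
        probs = calibrate_assessment_counts(2.10, 0.09)
        rng = np.random.default_rng(1)
        for _ in range(200):
            waves = missingness_engine(rng, probs, np.array([0.3, 0.2, 0.16, 0.46]))
            assert waves[0] == 1
            assert 2 <= len(waves) <= 5
            assert waves == sorted(set(waves))

    def test_mean_assessments_calibrated(self):
        cfg = default_study_config(4000)
        _, truth = generate_cohort(cfg, seed=13)
        assert truth["n_assessments"].mean() == pytest.approx(2.10, abs=0.08)
        assert (truth["n_assessments"] >= 3).mean() == pytest.approx(0.09, abs=0.02)


class TestGenerateCohort:
    def test_single_class_marginals_match_model(self):
        """With one class, empirical wave-category frequencies converge to the
        ordered-logit marginals (closed-form check at N=5000)."""
        from ordlcga import ClassGrowthParams, MixtureSpec

        spec = MixtureSpec(
            np.array([1.0]),
            [ClassGrowthParams(-0.5, 1.2, np.array([0.0, 0.3, 0.5, 0.8, 1.0]))],
            np.array([-1.5, 0.0, 1.5]),
        )
        cfg = CohortConfig(
            n=5000, spec=spec, class_names=["only"],
            continuous={}, binary={}, categorical={},
            distal_means=[0.0], distal_sd=1.0, apply_missingness=False,
        )
        _, truth = generate_cohort(cfg, seed=2)
        for t in range(5):
            want = category_probs(spec.classes[0].eta[t], spec.thresholds)
            got = (
                truth[f"y{t + 1}"].value_counts(normalize=True)
                .reindex([1, 2, 3, 4], fill_value=0.0).to_numpy()
            )
            np.testing.assert_allclose(got, want, atol=0.03)

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = default_study_config(150)
        a, _ = generate_cohort(cfg, seed=4)
        b, _ = generate_cohort(cfg, seed=4)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.to_csv(pa, index=False)
        b.to_csv(pb, index=False)
        assert pa.read_bytes() == pb.read_bytes()

    def test_growing_n_extends_stream(self):
        cfg_small = default_study_config(60)
        cfg_big = default_study_config(120)
        small, _ = generate_cohort(cfg_small, seed=5)
        big, _ = generate_cohort(cfg_big, seed=5)
        prefix = big[big["participant_id"].isin(small["participant_id"])]
        pd.testing.assert_frame_equal(
            small.reset_index(drop=True), prefix.reset_index(drop=True)
        )

    def test_round_trip_through_preprocessing(self, small_cohort):
        """Bucketing the generated long records reproduces the generated wave
        categories exactly."""
        long_df, truth = small_cohort
        wide = build_cohort(long_df)
        merged = wide.merge(truth, on="participant_id", suffixes=("", "_t"))
        assert len(merged) == len(truth)
        for t in range(1, 6):
            obs = merged[f"obs{t}"] == 1
            assert (merged.loc[obs, f"y{t}"] == merged.loc[obs, f"y{t}_t"]).all()
            assert (merged.loc[~obs, f"y{t}"] == 0).all()

    def test_class_conditional_covariates(self):
        cfg = default_study_config(4000)
        _, truth = generate_cohort(cfg, seed=6)
        long_df, _ = generate_cohort(cfg, seed=6)
        base = long_df.drop_duplicates("participant_id").merge(truth, on="participant_id")
        chronic = base[base["class_name"] == "chronic"]
        minimal = base[base["class_name"] == "minimal"]
        # published class means: chronic sleep quality 4.61, minimal 7.44
        assert chronic["sleep_quality"].mean() == pytest.approx(4.61, abs=0.5)
        assert minimal["sleep_quality"].mean() == pytest.approx(7.44, abs=0.2)
        assert chronic["treatment"].mean() > minimal["treatment"].mean()


class TestDefaultConfig:
    def test_published_defaults(self):
        cfg = default_study_config(100)
        assert cfg.continuous["sleep_quality"]["by_class"][CLASS_NAMES.index("chronic")] == 4.61
        w = cfg.spec.weights
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        # renormalized from a printed total of 100.01%
        assert w[0] == pytest.approx(0.6366 / 1.0001, abs=1e-4)
        assert "CLASS_PROPORTIONS_PCT" in PROVENANCE

    def test_yaml_round_trip(self):
        cfg = default_study_config(250)
        clone = CohortConfig.from_dict(yaml.safe_load(yaml.safe_dump(cfg.to_dict())))
        assert clone.n == cfg.n
        np.testing.assert_allclose(clone.spec.weights, cfg.spec.weights)
        np.testing.assert_allclose(clone.wave_propensities, cfg.wave_propensities)
        assert clone.binary == cfg.binary
        long_a, _ = generate_cohort(cfg, seed=8)
        long_b, _ = generate_cohort(clone, seed=8)
        pd.testing.assert_frame_equal(long_a, long_b)

    def test_invalid_configs_rejected(self):
        cfg = default_study_config(100)
        with pytest.raises(ValueError):
            CohortConfig.from_dict({**cfg.to_dict(), "n": 0})
        bad = cfg.to_dict()
        bad["wave_propensities"] = [-1.0, 0.5, 0.2, 0.3]
        with pytest.raises(ValueError):
            CohortConfig.from_dict(bad)


def test_covariate_tilt_recovery():
    """Planted covariate-linked missingness is recovered by the
    assessment-count logistic model."""
    from ordlcga import assessment_count_model

    cfg = default_study_config(6000)
    cfg.missingness_tilt = {"treatment": 1.0}
    long_df, truth = generate_cohort(cfg, seed=10)
    base = long_df.drop_duplicates("participant_id").merge(
        truth[["participant_id", "n_assessments"]], on="participant_id"
    )
    res = assessment_count_model(
        base[["treatment", "age"]], base["n_assessments"].to_numpy()
    )
    lo = res.loc["treatment", "coef"] - 2.5 * res.loc["treatment", "se"]
    hi = res.loc["treatment", "coef"] + 2.5 * res.loc["treatment", "se"]
    assert lo < 1.0 < hi
    assert abs(res.loc["age", "coef"]) < 3 * res.loc["age", "se"] + 0.02
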