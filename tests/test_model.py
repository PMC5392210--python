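"""Likelihood, category probabilities, and posterior of the ordinal mixture."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from ordlcga import (
    ClassGrowthParams,
    MixtureSpec,
    category_probs,
    linear_predictor,
    mixture_loglik,
    person_loglik_by_class,
    posterior,
)
from ordlcga.reference import published_spec


class TestLinearPredictor:
    def test_published_minimal_class(self):
        spec = published_spec()
        minimal = spec.classes[0]
        assert linear_predictor(minimal, 1) == pytest.approx(-51.05)
        assert linear_predictor(minimal, 5) == pytest.approx(-51.05 + 6.12)

    def test_zero_slope_constant(self):
        p = ClassGrowthParams(1.3, 0.0)
        assert all(linear_predictor(p, w) == pytest.approx(1.3) for w in range(1, 6))

    def test_bad_wave(self):
        with pytest.raises(ValueError):
            linear_predictor(ClassGrowthParams(0, 1), 6)


class TestCategoryProbs:
    def test_median_at_middle_threshold(self):
        tau = np.array([-2.0, 0.5, 3.0])
        p = category_probs(0.5, tau)
        assert p[:2].sum() == pytest.approx(0.5, abs=1e-12)

    def test_extreme_eta_limits(self):
        tau = np.array([-1.0, 0.0, 1.0])
        np.testing.assert_allclose(category_probs(-1e3, tau), [1, 0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(category_probs(1e3, tau), [0, 0, 0, 1], atol=1e-12)

    def test_published_threshold_arithmetic(self):
        # eta at the middle published threshold: cumulative probabilities are
        # logistic(-7.99), 0.5 and logistic(7.12)
        tau = np.array([-43.01, -35.02, -27.90])
        p = category_probs(-35.02, tau)
        assert p[0] == pytest.approx(expit(-7.99), rel=1e-12)
        assert p[:2].sum() == pytest.approx(0.5, abs=1e-12)
        assert p[:3].sum() == pytest.approx(expit(7.12), rel=1e-12)

    def test_nonincreasing_thresholds_rejected(self):
        with pytest.raises(ValueError):
            category_probs(0.0, np.array([0.0, 0.0, 1.0]))

    @given(st.floats(-200, 200))
    @settings(max_examples=100, deadline=None)
    def test_sums_to_one(self, eta):
        p = category_probs(eta, np.array([-1.5, 0.2, 2.0]))
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert (p >= 0).all()


class TestSpecValidation:
    def test_nominal_param_count(self, two_class_spec):
        assert two_class_spec.n_params == 14
        assert published_spec().n_params == 32
        one = MixtureSpec(
            np.array([1.0]), [ClassGrowthParams(0, 1)], np.array([-1.0, 0.0, 1.0])
        )
        assert one.n_params == 8

    def test_loading_endpoints_enforced(self):
        with pytest.raises(ValueError):
            ClassGrowthParams(0, 1, np.array([0.1, 0.2, 0.5, 0.8, 1.0]))
        with pytest.raises(ValueError):
            ClassGrowthParams(0, 1, np.array([0.0, 0.2, 0.5, 0.8, 0.9]))

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            MixtureSpec(
                np.array([0.6, 0.6]),
                [ClassGrowthParams(0, 1), ClassGrowthParams(1, 1)],
                np.array([-1.0, 0.0, 1.0]),
            )

    def test_serialization_round_trip(self, two_class_spec):
        clone = MixtureSpec.from_dict(two_class_spec.to_dict())
        np.testing.assert_allclose(clone.weights, two_class_spec.weights)
        np.testing.assert_allclose(clone.thresholds, two_class_spec.thresholds)
        for a, b in zip(clone.classes, two_class_spec.classes):
            assert a.intercept == b.intercept
            np.testing.assert_allclose(a.loadings, b.loadings)


def _brute_person_loglik(y_row, spec):
    """Oracle: per-class product of per-wave category probabilities."""
    out = []
    for c in range(spec.n_classes):
        eta = spec.classes[c].eta
        prob = 1.0
        for t, cat in enumerate(y_row):
            if cat > 0:
                prob *= category_probs(eta[t], spec.thresholds)[cat - 1]
        out.append(np.log(prob))
    return np.array(out)


class TestPersonLoglik:
    def test_matches_brute_force_product(self, two_class_spec):
        y = np.array([[1, 2, 0, 3, 4], [2, 0, 0, 0, 1], [4, 4, 3, 2, 1]])
        got = person_loglik_by_class(y, two_class_spec)
        want = np.vstack([_brute_person_loglik(r, two_class_spec) for r in y])
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_single_wave_equals_category_logprob(self, two_class_spec):
        y = np.array([[0, 0, 3, 0, 0]])
        got = person_loglik_by_class(y, two_class_spec)[0]
        for c in range(2):
            eta = two_class_spec.classes[c].eta[2]
            want = np.log(category_probs(eta, two_class_spec.thresholds)[2])
            assert got[c] == pytest.approx(want, abs=1e-12)

    def test_symmetric_classes_equal_entries(self):
        classes = [ClassGrowthParams(-1.0, 0.0), ClassGrowthParams(1.0, 0.0)]
        spec = MixtureSpec(np.array([0.5, 0.5]), classes, np.array([-2.0, 0.0, 2.0]))
        # category 2 at baseline only: P(Y=2 | eta=-1) = P(Y=3 | eta=1) but
        # symmetry of the logistic makes P(Y<=2|-1) = P(Y>2|1); use the
        # middle category pair symmetric around 0
        ll = person_loglik_by_class(np.array([[2, 0, 0, 0, 0]]), spec)[0]
        ll_mirror = person_loglik_by_class(np.array([[3, 0, 0, 0, 0]]), spec)[0]
        assert ll[0] == pytest.approx(ll_mirror[1], abs=1e-12)

    def test_bad_category_rejected(self, two_class_spec):
        with pytest.raises(ValueError):
            person_loglik_by_class(np.array([[5, 0, 0, 0, 0]]), two_class_spec)


class TestMixtureLoglik:
    def test_k1_reduces_to_sum(self):
        spec = MixtureSpec(
            np.array([1.0]), [ClassGrowthParams(-0.5, 1.0)], np.array([-1.0, 0.0, 1.0])
        )
        y = np.array([[1, 2, 3, 4, 1], [2, 2, 0, 0, 1]])
        assert mixture_loglik(y, spec) == pytest.approx(
            person_loglik_by_class(y, spec).sum(), abs=1e-10
        )

    def test_matches_direct_enumeration(self, two_class_spec):
        y = np.array([[1, 2, 0, 3, 4], [4, 0, 0, 0, 1]])
        want = 0.0
        for row in y:
            lik = 0.0
            for c, w in enumerate(two_class_spec.weights):
                lik += w * np.exp(_brute_person_loglik(row, two_class_spec)[c])
            want += np.log(lik)
        assert mixture_loglik(y, two_class_spec) == pytest.approx(want, abs=1e-10)

    def test_duplication_doubles(self, two_class_spec):
        y = np.array([[1, 2, 3, 2, 1], [2, 0, 0, 0, 4]])
        assert mixture_loglik(np.vstack([y, y]), two_class_spec) == pytest.approx(
            2 * mixture_loglik(y, two_class_spec), rel=1e-12
        )

    def test_class_duplication_invariance(self, two_class_spec):
        y = np.array([[1, 2, 3, 2, 1], [2, 0, 0, 0, 4], [3, 3, 3, 3, 3]])
        c0, c1 = two_class_spec.classes
        split = MixtureSpec(
            np.array([0.6, 0.2, 0.2]),
            [c0, c1, ClassGrowthParams(c1.intercept, c1.slope, c1.loadings.copy())],
            two_class_spec.thresholds.copy(),
        )
        assert mixture_loglik(y, split) == pytest.approx(
            mixture_loglik(y, two_class_spec), abs=1e-10
        )

    def test_location_invariance(self, two_class_spec):
        """Shifting every intercept and threshold by a constant leaves the
        likelihood unchanged — the identification gap closed by the anchor."""
        y = np.array([[1, 2, 3, 2, 1], [2, 0, 0, 0, 4], [4, 4, 4, 4, 4]])
        base = mixture_loglik(y, two_class_spec)
        for delta in (-7.3, 0.01, 12.0):
            shifted = two_class_spec.shifted(two_class_spec.thresholds[1] + delta)
            assert mixture_loglik(y, shifted) == pytest.approx(base, abs=1e-8)


class TestPosterior:
    def test_k1_all_ones(self):
        spec = MixtureSpec(
            np.array([1.0]), [ClassGrowthParams(0, 1)], np.array([-1.0, 0.0, 1.0])
        )
        p = posterior(np.array([[1, 2, 3, 0, 0]]), spec)
        np.testing.assert_allclose(p, [[1.0]])

    def test_flat_evidence_returns_prior(self):
        classes = [ClassGrowthParams(0.7, 0.0), ClassGrowthParams(0.7, 0.0)]
        spec = MixtureSpec(np.array([0.3, 0.7]), classes, np.array([-1.0, 0.0, 1.0]))
        p = posterior(np.array([[2, 3, 2, 0, 1]]), spec)
        np.testing.assert_allclose(p[0], [0.3, 0.7], atol=1e-12)

    def test_hand_bayes_two_class(self, two_class_spec):
        y = np.array([[1, 0, 0, 0, 4]])
        lik = np.exp(_brute_person_loglik(y[0], two_class_spec))
        want = two_class_spec.weights * lik
        want = want / want.sum()
        np.testing.assert_allclose(posterior(y, two_class_spec)[0], want, atol=1e-12)

    def test_rows_sum_to_one(self, two_class_spec, two_class_data):
        y, _ = two_class_data
        p = posterior(y[:200], two_class_spec)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert (p >= 0).all() and (p <= 1).all()
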