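"""Error-corrected 3-step analysis: assignment, error matrix, prediction,
distal comparison, screening, effect size."""

import numpy as np
import pandas as pd
import pytest

from ordlcga import (
    classification_error,
    cohen_d,
    modal_assign,
    screen_predictors,
    standardize_predictors,
    step3_distal,
    step3_predictors,
)
from ordlcga.three_step import ClassificationErrorMatrix, _SENTINEL


class TestModalAssign:
    def test_argmax_and_tie_rule(self):
        post = np.array([[0.1, 0.9], [0.5, 0.5], [0.7, 0.3]])
        np.testing.assert_array_equal(modal_assign(post), [1, 0, 0])

    def test_modal_proportions_track_posterior_means(self, two_class_spec, two_class_data):
        from ordlcga import posterior

        y, _ = two_class_data
        p = posterior(y, two_class_spec)
        modal = modal_assign(p)
        modal_prop = np.bincount(modal, minlength=2) / len(modal)
        np.testing.assert_allclose(modal_prop, p.mean(axis=0), atol=0.03)


class TestClassificationError:
    def test_perfect_posterior_gives_identity(self):
        post = np.eye(3)[np.array([0, 1, 2, 1, 0])]
        err = classification_error(post)
        np.testing.assert_allclose(err.q, np.eye(3), atol=1e-12)
        # measurement logits dominate by the sentinel magnitude per column
        for c in range(3):
            others = [err.logits[s, c] for s in range(3) if s != c]
            assert err.logits[c, c] - max(others) >= abs(_SENTINEL) - 1e-6

    def test_constant_rows_give_modal_frequencies(self):
        # when every row has the same posterior, q columns all equal the
        # modal-label frequencies (independence case)
        rng = np.random.default_rng(3)
        modal = rng.choice(3, size=60)
        post = np.tile([0.5, 0.3, 0.2], (60, 1))
        err = classification_error(post, modal)
        freq = np.bincount(modal, minlength=3) / 60
        for c in range(3):
            np.testing.assert_allclose(err.q[:, c], freq, atol=1e-12)

    def test_three_row_hand_computation(self):
        post = np.array([[0.8, 0.2], [0.3, 0.7], [0.6, 0.4]])
        modal = np.array([0, 1, 0])
        err = classification_error(post, modal)
        # column totals: class1 = 1.7, class2 = 1.3
        np.testing.assert_allclose(err.q[:, 0], [1.4 / 1.7, 0.3 / 1.7], atol=1e-12)
        np.testing.assert_allclose(err.q[:, 1], [0.6 / 1.3, 0.7 / 1.3], atol=1e-12)
        assert err.q.sum(axis=0) == pytest.approx([1.0, 1.0])

    def test_empty_modal_class_warns(self):
        post = np.tile([0.9, 0.1], (5, 1))
        with pytest.warns(UserWarning, match="empty"):
            classification_error(post)


def _simulate_soft_classes(n, beta, entropy_noise, seed):
    """True class from a logistic model of x; posterior blurred by noise."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    p1 = 1 / (1 + np.exp(-(0.3 + beta * x)))
    true = (rng.random(n) < p1).astype(int)
    # imperfect posterior: correct class gets weight q < 1
    q_correct = 1 - entropy_noise
    post = np.where(
        true[:, None] == np.arange(2)[None, :], q_correct, 1 - q_correct
    )
    noisy_modal = np.where(rng.random(n) < q_correct, true, 1 - true)
    return x, true, post, noisy_modal


class TestStep3Predictors:
    def test_identity_error_matches_standard_multinomial(self):
        """With a perfect error matrix, step 3 equals ordinary multinomial
        logistic regression on the modal labels (statsmodels oracle)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        n = 800
        x = rng.normal(size=(n, 2))
        lin = np.column_stack([np.zeros(n), 0.8 * x[:, 0] - 0.5 * x[:, 1],
                               -0.4 * x[:, 0] + 0.9 * x[:, 1]])
        p = np.exp(lin) / np.exp(lin).sum(axis=1, keepdims=True)
        labels = np.array([rng.choice(3, p=row) for row in p])
        err = ClassificationErrorMatrix.identity(3)
        res = step3_predictors(labels, err, pd.DataFrame(x, columns=["a", "b"]))
        oracle = sm.MNLogit(labels, sm.add_constant(x)).fit(disp=0, maxiter=200)
        ours = (
            res.coefficients.sort_values(["class_index", "predictor"])
            .set_index(["class_index", "predictor"])["log_odds"]
        )
        params = np.asarray(oracle.params)
        for j, cls in enumerate([1, 2]):
            want = params[:, j]  # const, a, b
            got = np.array(
                [ours[(cls, "intercept")], ours[(cls, "a")], ours[(cls, "b")]]
            )
            np.testing.assert_allclose(got, want, atol=1e-6)

    def test_published_odds_ratio_arithmetic(self):
        # the log-odds -> odds-ratio identity at the published stress value
        assert np.exp(0.55) == pytest.approx(1.73, abs=0.01)

    def test_exponentiation_identity_on_output(self):
        x, _, post, modal = _simulate_soft_classes(500, 1.0, 0.2, 4)
        err = classification_error(post, modal)
        res = step3_predictors(modal, err, pd.DataFrame({"x": x}))
        np.testing.assert_allclose(
            res.coefficients["odds_ratio"],
            np.exp(res.coefficients["log_odds"]),
            rtol=1e-12,
        )

    def test_null_predictor_near_zero(self):
        rng = np.random.default_rng(10)
        n = 1500
        modal = rng.choice(2, size=n, p=[0.6, 0.4])
        x = rng.normal(size=n)  # independent of class
        err = ClassificationErrorMatrix.identity(2)
        res = step3_predictors(modal, err, pd.DataFrame({"x": x}))
        row = res.coefficients.query("predictor == 'x'").iloc[0]
        assert abs(row["log_odds"]) < 3 * row["se"] + 0.1
        assert row["p"] > 0.001

    def test_contrast_equals_coefficient_difference(self):
        rng = np.random.default_rng(12)
        n = 900
        x = rng.normal(size=(n, 1))
        lin = np.column_stack([np.zeros(n), 0.7 * x[:, 0], -0.6 * x[:, 0]])
        p = np.exp(lin) / np.exp(lin).sum(axis=1, keepdims=True)
        labels = np.array([rng.choice(3, p=row) for row in p])
        err = ClassificationErrorMatrix.identity(3)
        res = step3_predictors(
            labels, err, pd.DataFrame(x, columns=["x"]),
            reference=0, contrast_pairs=[(2, 1)],
        )
        coef = res.coefficients.set_index(["class_index", "predictor"])["log_odds"]
        got = res.contrasts.query("predictor == 'x'")["log_odds"].iloc[0]
        assert got == pytest.approx(coef[(2, "x")] - coef[(1, "x")], abs=1e-12)
        # and it matches a refit using class 1 as the reference
        res_b = step3_predictors(labels, err, pd.DataFrame(x, columns=["x"]),
                                 reference=1)
        refit = res_b.coefficients.set_index(["class_index", "predictor"])["log_odds"]
        assert got == pytest.approx(refit[(2, "x")], abs=1e-6)

    def test_correction_beats_naive_under_entropy(self):
        """With imperfect classification, 3-step estimates are less
        attenuated than naive regression on modal labels."""
        x, true, post, modal = _simulate_soft_classes(4000, 1.0, 0.15, 17)
        q = np.full((2, 2), 0.15)
        np.fill_diagonal(q, 0.85)
        err = ClassificationErrorMatrix(q=q, logits=np.log(q / q[-1]))
        corrected = step3_predictors(modal, err, pd.DataFrame({"x": x}))
        naive = step3_predictors(
            modal, ClassificationErrorMatrix.identity(2), pd.DataFrame({"x": x})
        )
        b_corr = corrected.coefficients.query("predictor=='x'")["log_odds"].iloc[0]
        b_naive = naive.coefficients.query("predictor=='x'")["log_odds"].iloc[0]
        assert abs(b_corr) > abs(b_naive)


class TestStep3Distal:
    def test_identity_error_equals_group_means(self):
        rng = np.random.default_rng(5)
        modal = rng.choice(2, size=400)
        y = np.where(modal == 0, 0.0, 2.0) + rng.normal(0, 1, 400)
        err = ClassificationErrorMatrix.identity(2)
        res = step3_distal(modal, err, y)
        means = res.distal["mean"].to_numpy()
        assert means[0] == pytest.approx(y[modal == 0].mean(), abs=1e-6)
        assert means[1] == pytest.approx(y[modal == 1].mean(), abs=1e-6)

    def test_effect_size_recovery(self):
        rng = np.random.default_rng(6)
        n = 3000
        true = rng.choice(2, size=n, p=[0.5, 0.5])
        y = true * 1.0 + rng.normal(0, 1, n)
        q = np.full((2, 2), 0.1)
        np.fill_diagonal(q, 0.9)
        modal = np.where(rng.random(n) < 0.9, true, 1 - true)
        err = ClassificationErrorMatrix(q=q, logits=np.log(q / q[-1]))
        res = step3_distal(modal, err, y)
        pair = res.distal_pairs.query("`class`=='class_2' and vs=='class_1'").iloc[0]
        assert pair["cohen_d"] == pytest.approx(1.0, abs=0.15)
        assert pair["p"] < 1e-6

    def test_null_difference(self):
        rng = np.random.default_rng(7)
        modal = rng.choice(2, size=1000)
        y = rng.normal(size=1000)
        res = step3_distal(modal, ClassificationErrorMatrix.identity(2), y)
        pair = res.distal_pairs.iloc[0]
        assert abs(pair["mdiff"]) < 0.2
        assert pair["p"] > 0.01

    def test_missing_outcomes_tolerated(self):
        rng = np.random.default_rng(8)
        modal = rng.choice(2, size=300)
        y = np.where(modal == 0, 0.0, 1.5) + rng.normal(0, 1, 300)
        y[rng.random(300) < 0.3] = np.nan
        res = step3_distal(modal, ClassificationErrorMatrix.identity(2), y)
        assert np.isfinite(res.distal["mean"]).all()


class TestScreening:
    def test_null_out_strong_in_empty_passthrough(self):
        rng = np.random.default_rng(9)
        n = 2500
        true = rng.choice(2, size=n, p=[0.6, 0.4])
        strong = true * 1.2 + rng.normal(0, 1, n)
        null = rng.normal(size=n)
        err = ClassificationErrorMatrix.identity(2)
        kept = screen_predictors(
            true, err, pd.DataFrame({"strong": strong, "null": null}),
            focal_pairs=[(1, 0)],
        )
        assert kept == ["strong"]
        assert screen_predictors(true, err, pd.DataFrame(), [(1, 0)]) == []


class TestCohenD:
    def test_identical_groups_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert cohen_d(x, x) == 0.0

    def test_unit_case(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, 100_00)
        a = (a - a.mean()) / a.std(ddof=1)
        b = a + 1.0
        assert cohen_d(b, a) == pytest.approx(1.0, abs=1e-10)

    def test_hand_arithmetic(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0])
        pooled = np.sqrt(((2) * 1.0 + (1) * 2.0) / 3)
        assert cohen_d(a, b) == pytest.approx((2.0 - 3.0) / pooled, abs=1e-12)

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            cohen_d([1.0], [1.0, 2.0])


def test_standardize_excludes_age_and_sleep_hours():
    df = pd.DataFrame(
        {"age": [30.0, 50.0], "stress": [2.0, 6.0], "sleep_hours": [6.0, 8.0]}
    )
    out = standardize_predictors(df, ["age", "stress", "sleep_hours"])
    pd.testing.assert_series_equal(out["age"], df["age"])
    pd.testing.assert_series_equal(out["sleep_hours"], df["sleep_hours"])
    assert out["stress"].std(ddof=1) == pytest.approx(1.0)
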