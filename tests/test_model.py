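"""PLS core, sMC importance, ROC cutoff and the Model/Results surface."""

import numpy as np
import pandas as pd
import pytest

from docprog.exceptions import ConfigurationError
from docprog.model import (
    ModelConfig,
    PrognosticPLSModel,
    PrognosticPLSResults,
    choose_n_latent,
    fit_plsr,
    roc_cutoff,
    smc_importance,
)
from docprog.synthetic import CohortSpec, gen_cohort


def brute_force_cutoff(scores, labels):
    """Exhaustive threshold search oracle for roc_cutoff."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos, neg = scores[labels], scores[~labels]
    uniq = np.unique(scores)
    cands = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2, [np.inf]])
    best = None
    for c in cands:
        sens = (pos >= c).mean()
        spec = (neg < c).mean()
        key = (sens + spec, spec, -c)
        if best is None or key > best[0]:
            best = (key, c)
    return best[1]


class TestFitPlsr:
    def test_constant_response_gives_zero_coefficients(self, rng):
        X = rng.standard_normal((15, 4))
        coef, icpt = fit_plsr(X, np.full(15, 6.0), 2)
        assert np.all(coef == 0) and icpt == 6.0

    def test_full_rank_matches_normal_equations(self, rng):
        n, q = 20, 3
        X = rng.standard_normal((n, q))
        y = rng.standard_normal(n)
        coef, icpt = fit_plsr(X, y, n_latent=q)
        Xi = np.column_stack([np.ones(n), X])
        beta = np.linalg.solve(Xi.T @ Xi, Xi.T @ y)
        np.testing.assert_allclose(icpt + X @ coef, Xi @ beta, atol=1e-8)

    def test_single_predictor_proportional_to_response(self, rng):
        x = rng.standard_normal(25)
        X = x[:, None]
        y = 2.5 * x + 1.0
        coef, icpt = fit_plsr(X, y, 1)
        np.testing.assert_allclose(icpt + X @ coef, y, atol=1e-10)

    def test_excess_latent_variables_reduced_to_rank(self, rng):
        X = rng.standard_normal((20, 3))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])  # rank 3
        y = rng.standard_normal(20)
        with pytest.warns(UserWarning, match="rank"):
            coef, icpt = fit_plsr(X, y, n_latent=4)
        assert np.isfinite(coef).all()


class TestChooseNLatent:
    def test_noiseless_low_rank_response(self, rng):
        n = 200
        latent = rng.standard_normal((n, 2))
        X = latent @ rng.standard_normal((2, 8)) + 0.01 * rng.standard_normal((n, 8))
        y = latent @ np.array([1.0, -2.0])
        assert choose_n_latent(X, y, max_lv=6) <= 3

    def test_pure_noise_prefers_one_component(self, rng):
        X = rng.standard_normal((60, 10))
        y = rng.standard_normal(60)
        assert choose_n_latent(X, y, max_lv=6) == 1

    def test_too_many_folds_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            choose_n_latent(rng.standard_normal((4, 3)), np.zeros(4), folds=5)


class TestSmcImportance:
    def test_orthogonal_predictor_gets_zero(self):
        n = 40
        t = np.linspace(0, 2 * np.pi, n)
        x1 = np.sin(t)
        x2 = np.cos(t)  # orthogonal to x1 (and to yhat = x1 direction)
        X = np.column_stack([x1, x2])
        f = smc_importance(X, x1, np.array([1.0, 0.0]))
        assert f[1] < 1e-10 and f[0] > 1e3

    def test_collinear_predictor_flagged_infinite(self, rng):
        x = rng.standard_normal(30)
        X = np.column_stack([x, rng.standard_normal(30)])
        f = smc_importance(X, x, np.array([1.0, 0.0]))
        assert np.isinf(f[0])

    def test_informative_outrank_noise(self):
        successes = 0
        for seed in range(20):
            g = np.random.default_rng(seed)
            X = g.standard_normal((100, 20))
            y = X[:, :5] @ np.ones(5) + g.normal(0, 0.5, 100)
            coef, _ = fit_plsr((X - X.mean(0)) / X.std(0), y, 3)
            f = smc_importance(X, y, coef)
            if np.median(f[:5]) > f[5:].max():
                successes += 1
        assert successes >= 18

    def test_zero_coefficients_give_zero_importance(self, rng):
        X = rng.standard_normal((20, 4))
        f = smc_importance(X, rng.standard_normal(20), np.zeros(4))
        assert np.all(f == 0)


class TestRocCutoff:
    def test_perfect_separation(self):
        scores = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        labels = np.array([0, 0, 0, 1, 1, 1], dtype=bool)
        res = roc_cutoff(scores, labels)
        assert res.auc == 1.0
        assert 3 < res.cutoff < 10
        assert ((scores >= res.cutoff) == labels).all()

    def test_null_auc_near_half(self, rng):
        scores = rng.standard_normal(4000)
        labels = rng.random(4000) < 0.5
        assert abs(roc_cutoff(scores, labels).auc - 0.5) < 0.05

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(6, 40))
            scores = np.round(rng.standard_normal(n), 2)  # force ties
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            assert roc_cutoff(scores, labels).cutoff == brute_force_cutoff(
                scores, labels
            )

    def test_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = np.round(rng.standard_normal(300), 1)
        labels = rng.random(300) < 0.3
        assert np.isclose(
            roc_cutoff(scores, labels).auc, roc_auc_score(labels, scores)
        )

    def test_single_class_rejected(self):
        with pytest.raises(ConfigurationError):
            roc_cutoff(np.arange(5.0), np.ones(5, bool))


class TestModelResults:
    @pytest.fixture(scope="class")
    def fitted(self):
        _, table, _ = gen_cohort(CohortSpec(seed=21))
        model = PrognosticPLSModel.from_dataframe(table)
        return table, model.fit(seed=0)

    def test_training_scores_reproduce_bit_for_bit(self, fitted):
        table, res = fitted
        patients = table[table["group"] == "patient"]
        pred = res.predict(patients)["predicted_score"].to_numpy()
        np.testing.assert_array_equal(pred, res.fitted_scores)

    def test_subject_at_training_means_scores_intercept(self, fitted):
        _, res = fitted
        row = pd.DataFrame([res.train_means], columns=res.feature_names)
        pred = res.predict(row)
        assert np.isclose(pred["predicted_score"].iloc[0], res.intercept)

    def test_score_equal_to_cutoff_labels_recovery(self, fitted):
        _, res = fitted
        # invert: build a synthetic feature row whose score is the cutoff
        target = res.cutoff
        j = int(np.argmax(np.abs(res.coefficients)))
        x = res.train_means.copy()
        x[j] += (
            (target - res.intercept)
            / res.coefficients[j]
            * res.train_sds[j]
        )
        row = pd.DataFrame([x], columns=res.feature_names)
        out = res.predict(row)
        assert np.isclose(out["predicted_score"].iloc[0], target)
        assert out["label"].iloc[0] == "recovery"

    def test_hand_computed_three_feature_score(self):
        res = PrognosticPLSResults(
            model=None,
            feature_names=["a", "b", "c"],
            imaging_feature_names=["a"],
            train_means=np.array([1.0, 2.0, 3.0]),
            train_sds=np.array([2.0, 1.0, 4.0]),
            n_latent=1,
            coefficients=np.array([0.5, -1.0, 2.0]),
            intercept=10.0,
            cutoff=None,
            auc=None,
            smc_f=np.zeros(3),
            rsquared=0.0,
        )
        row = pd.DataFrame([[3.0, 1.0, 11.0]], columns=["a", "b", "c"])
        expected = 10.0 + 0.5 * 1.0 + (-1.0) * (-1.0) + 2.0 * 2.0
        out = res.predict(row)
        assert abs(out["predicted_score"].iloc[0] - expected) < 1e-12
        assert abs(out["imaging_subscore"].iloc[0] - 0.5) < 1e-12

    def test_monotone_in_feature_with_coefficient_sign(self, fitted):
        _, res = fitted
        j = int(np.argmax(res.coefficients))
        lo = pd.DataFrame([res.train_means], columns=res.feature_names)
        hi = lo.copy()
        hi.iloc[0, j] += 1.0
        assert (
            res.predict(hi)["predicted_score"].iloc[0]
            > res.predict(lo)["predicted_score"].iloc[0]
        )

    def test_missing_feature_rejected(self, fitted):
        _, res = fitted
        row = pd.DataFrame([[0.0]], columns=["nope"])
        with pytest.raises(ConfigurationError, match=res.feature_names[0][:6]):
            res.predict(row)

    def test_json_round_trip(self, fitted, tmp_path):
        _, res = fitted
        path = tmp_path / "model.json"
        res.to_json(path)
        loaded = PrognosticPLSResults.from_json(path)
        np.testing.assert_array_equal(loaded.coefficients, res.coefficients)
        np.testing.assert_array_equal(loaded.train_means, res.train_means)
        assert loaded.cutoff == res.cutoff
        assert loaded.feature_names == res.feature_names

    def test_summary_mentions_key_quantities(self, fitted):
        _, res = fitted
        text = res.summary()
        assert "latent" in text and "R^2" in text
        assert res.feature_names[0] in text


class TestDmnEcnCoefficientSign:
    def test_anticorrelation_feature_gets_negative_weight(self):
        """The default-mode x executive connectivity, when selected, takes a
        negative coefficient (loss of anti-correlation predicts worse
        outcome)."""
        spec = CohortSpec(seed=0)
        fc_name = spec.feature_names[spec.roi_count + spec.dmn_ecn_pairs()[0]]
        negatives = selected = 0
        for seed in range(6):
            _, table, _ = gen_cohort(CohortSpec(seed=100 + seed))
            res = PrognosticPLSModel.from_dataframe(table).fit(seed=seed)
            if fc_name in res.feature_names:
                selected += 1
                if res.params[fc_name] < 0:
                    negatives += 1
        assert selected >= 3
        assert negatives == selected
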