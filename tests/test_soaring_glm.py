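"""Binomial GLM fitting, AIC all-subsets ranking, model averaging, AUC.

The IRLS fits are cross-checked against a hand-rolled Newton-Raphson
oracle on a 200-row fixture; AUC against an O(n^2) all-pairs concordance
count; averaging against exactly computable worked cases.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from conftest import THERMAL_COEFS, OROGRAPHIC_COEFS, make_covariate_table
from soarscape import soaring_glm as sg
from soarscape import synthetic_data as sd


# ----------------------------------------------------------- response build


class TestBuildResponse:
    @staticmethod
    def labeled(n_thermal=10, n_oro=5, n_glide=5, n_perched=0):
        labels = (
            ["thermal_soaring"] * n_thermal
            + ["orographic_soaring"] * n_oro
            + ["gliding"] * n_glide
            + ["perched"] * n_perched
        )
        n = len(labels)
        rng = np.random.default_rng(1)
        return pd.DataFrame(
            {
                "behavior": labels,
                "elevation": rng.uniform(0, 1000, n),
                "slope": rng.uniform(0, 30, n),
                "wind_speed": rng.gamma(2, 2, n),
                "v": rng.uniform(0, 180, n),
                "hs": rng.uniform(0, 255, n),
                "temperature": rng.uniform(10, 30, n),
            }
        )

    def test_thermal_target_splits_ten_ten(self):
        y, cov = sg.build_response(self.labeled(), "thermal_soaring")
        assert y.sum() == 10
        assert len(y) == 20

    def test_orographic_target_splits_five_fifteen(self):
        y, cov = sg.build_response(self.labeled(), "orographic_soaring")
        assert y.sum() == 5
        assert len(y) == 20

    def test_perched_rows_violate_contract(self):
        with pytest.raises(ValueError, match="perched"):
            sg.build_response(self.labeled(n_perched=3), "thermal_soaring")

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError, match="no positive"):
            sg.build_response(self.labeled(n_thermal=0, n_oro=8), "thermal_soaring")

    def test_missing_covariates_dropped_and_counted(self):
        df = self.labeled()
        df.loc[0, "v"] = np.nan
        y, cov = sg.build_response(df, "thermal_soaring")
        assert len(y) == 19
        assert cov.attrs["n_dropped"] == 1


# ----------------------------------------------------------------- fitting


def _newton_logistic_oracle(y, X, tol=1e-12, max_iter=200):
    """Logistic MLE by straight Newton-Raphson on the score equations."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        p = expit(X @ beta)
        grad = X.T @ (y - p)
        W = p * (1 - p)
        hess = X.T @ (X * W[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


class TestFitGlm:
    def test_intercept_only_balanced_response_is_zero(self):
        y = np.array([0, 1] * 50)
        cov = pd.DataFrame(index=range(100))
        fit = sg.fit_glm(y, cov, ())
        assert fit.params["intercept"] == pytest.approx(0.0, abs=1e-8)

    def test_matches_newton_oracle_on_200_row_fixture(self):
        cov = make_covariate_table(200, seed=11)
        terms = ["elevation", "slope", "wind_speed", "hs"]
        y = sd.simulate_glm_response(
            5,
            cov,
            {"intercept": -0.5, "elevation": 5e-4, "slope": -0.03, "wind_speed": -0.1, "hs": 4e-3},
        )
        fit = sg.fit_glm(y, cov, terms)
        X = np.column_stack([np.ones(200)] + [cov[t].to_numpy() for t in terms])
        beta = _newton_logistic_oracle(y.astype(float), X)
        assert fit.params.to_numpy() == pytest.approx(beta, abs=1e-6)

    def test_aic_identity(self):
        cov = make_covariate_table(300, seed=2)
        y = sd.simulate_glm_response(1, cov, {"intercept": 0.2, "slope": -0.02})
        fit = sg.fit_glm(y, cov, ["slope", "wind_speed"])
        assert fit.aic == pytest.approx(-2 * fit.llf + 2 * fit.k, abs=1e-12)
        assert fit.k == 3

    def test_parameter_recovery_within_3se_thermal_and_orographic(self, recovery_data):
        cov = recovery_data["cov"]
        for resp, truth in (
            ("thermal", THERMAL_COEFS),
            ("orographic", OROGRAPHIC_COEFS),
        ):
            fit = sg.fit_glm(recovery_data[resp], cov, sg.CANDIDATE_TERMS)
            for term, true_val in truth.items():
                err = abs(fit.params[term] - true_val)
                assert err < 3 * fit.bse[term], f"{resp}:{term}"

    def test_underdetermined_fit_rejected(self):
        cov = make_covariate_table(5, seed=3)
        with pytest.raises(ValueError):
            sg.fit_glm(np.array([0, 1, 0, 1, 1]), cov, sg.CANDIDATE_TERMS)


# ------------------------------------------------------------- all subsets


class TestAllSubsetsAic:
    def test_marginality_prunes_orphan_quadratics(self):
        subsets = sg.admissible_subsets(["elevation", "elevation2", "slope", "slope2"])
        assert ("elevation2",) not in subsets
        for s in subsets:
            if "elevation2" in s:
                assert "elevation" in s
            if "slope2" in s:
                assert "slope" in s
        # 3 options for each variable pair: absent, linear, linear+quadratic
        assert len(subsets) == 9

    def test_ranked_sorted_weights_normalized(self, recovery_data):
        cov = recovery_data["cov"].iloc[:4000]
        y = recovery_data["thermal"][:4000]
        ranked = sg.all_subsets_aic(y, cov, ["slope", "slope2", "wind_speed", "hs"])
        aics = [f.aic for f in ranked]
        assert aics == sorted(aics)
        assert ranked[0].delta_aic == 0.0
        assert sum(f.weight for f in ranked) == pytest.approx(1.0, abs=1e-12)

    def test_dominant_effect_lands_in_top_model(self):
        cov = make_covariate_table(6000, seed=4)
        y = sd.simulate_glm_response(9, cov, {"intercept": -0.2, "slope": 0.08})
        ranked = sg.all_subsets_aic(y, cov, ["slope", "wind_speed", "temperature"])
        assert "slope" in ranked[0].terms


# ---------------------------------------------------------- model averaging


def _toy_fit(terms, params, bse, aic, n=100):
    names = ["intercept", *terms]
    return sg.FittedGlm(
        terms=tuple(terms),
        params=pd.Series([params.get(t, 0.0) for t in names], index=names),
        bse=pd.Series([bse.get(t, 0.1) for t in names], index=names),
        llf=-(aic - 2 * len(names)) / 2,
        k=len(names),
        aic=aic,
        n=n,
        converged=True,
    )


def _attach_weights(fits):
    best = min(f.aic for f in fits)
    rel = np.array([np.exp(-(f.aic - best) / 2) for f in fits])
    for f, w in zip(fits, rel / rel.sum()):
        f.delta_aic = f.aic - best
        f.weight = float(w)
    return sorted(fits, key=lambda f: f.aic)


class TestModelAverage:
    def test_single_model_in_window_returns_it_unchanged(self):
        fits = _attach_weights(
            [
                _toy_fit(["slope"], {"intercept": -0.5, "slope": 0.03}, {}, 100.0),
                _toy_fit(["wind_speed"], {"intercept": -0.2}, {}, 110.0),
            ]
        )
        avg = sg.model_average(fits)
        assert avg.n_models == 1
        assert avg.estimates["slope"] == pytest.approx(0.03)
        assert avg.estimates["intercept"] == pytest.approx(-0.5)

    def test_equal_aic_gives_half_half_weights(self):
        fits = _attach_weights(
            [
                _toy_fit(["slope"], {"intercept": 0.0, "slope": 1.0}, {}, 100.0),
                _toy_fit(["wind_speed"], {"intercept": 0.0, "wind_speed": 2.0}, {}, 100.0),
            ]
        )
        avg = sg.model_average(fits)
        assert avg.weights == pytest.approx([0.5, 0.5])

    def test_absent_term_halved_under_full_averaging(self):
        fits = _attach_weights(
            [
                _toy_fit(["slope"], {"intercept": 0.0, "slope": 1.0}, {}, 100.0),
                _toy_fit([], {"intercept": 0.0}, {}, 100.0),
            ]
        )
        avg = sg.model_average(fits)
        assert avg.estimates["slope"] == pytest.approx(0.5)
        # conditional averaging instead renormalizes over containing models
        cond = sg.model_average(fits, conditional=True)
        assert cond.estimates["slope"] == pytest.approx(1.0)

    def test_buckland_unconditional_se(self):
        fits = _attach_weights(
            [
                _toy_fit(["slope"], {"intercept": 0.0, "slope": 1.0}, {"slope": 0.2}, 100.0),
                _toy_fit([], {"intercept": 0.0}, {}, 100.0),
            ]
        )
        avg = sg.model_average(fits)
        # SE = 0.5*sqrt(0.2^2 + 0.5^2) + 0.5*sqrt(0 + 0.5^2)
        expected = 0.5 * np.sqrt(0.04 + 0.25) + 0.5 * 0.5
        assert avg.se["slope"] == pytest.approx(expected, abs=1e-12)
        assert avg.ci_low["slope"] == pytest.approx(0.5 - 1.96 * expected)

    def test_clear_top_model_short_circuits(self):
        fits = _attach_weights(
            [
                _toy_fit(["slope"], {"intercept": -1.0, "slope": 0.5}, {}, 100.0),
                _toy_fit([], {"intercept": 0.0}, {}, 120.0),
            ]
        )
        assert fits[0].weight > 0.9
        avg = sg.model_average(fits)
        assert avg.n_models == 1
        assert avg.estimates["slope"] == pytest.approx(0.5)

    def test_delta_exactly_two_excluded(self):
        fits = _attach_weights(
            [
                _toy_fit(["slope"], {"intercept": 0.0, "slope": 1.0}, {}, 100.0),
                _toy_fit(["wind_speed"], {"intercept": 0.0, "wind_speed": 1.0}, {}, 101.0),
                _toy_fit([], {"intercept": 0.0}, {}, 102.0),
            ]
        )
        avg = sg.model_average(fits)
        assert avg.n_models == 2  # the delta=2.0 model is strictly outside

    def test_shrinkage_bound_on_full_average(self, recovery_data):
        cov = recovery_data["cov"].iloc[:4000]
        y = recovery_data["thermal"][:4000]
        ranked = sg.all_subsets_aic(y, cov, ["slope", "slope2", "wind_speed", "hs", "temperature"])
        avg = sg.model_average(ranked)
        contributing = (
            [ranked[0]] if ranked[0].weight > 0.9 else [f for f in ranked if f.delta_aic < 2]
        )
        for term in avg.terms:
            max_mag = max(abs(f.params.get(term, 0.0)) for f in contributing)
            assert abs(avg.estimates[term]) <= max_mag + 1e-12

    def test_json_round_trip_preserves_predictions(self, averaged_models, recovery_data):
        avg = averaged_models["thermal"]
        clone = sg.AveragedModel.from_json(avg.to_json())
        cov = recovery_data["cov"].iloc[:100]
        assert clone.predict(cov) == pytest.approx(avg.predict(cov), abs=1e-12)


# --------------------------------------------------------------------- AUC


def _auc_pairs_oracle(y, s):
    """All-pairs concordance count, ties counted one half."""
    pos = s[y == 1]
    neg = s[y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_ranking_is_one(self):
        y = np.array([0] * 5 + [1] * 5)
        s = np.arange(10, dtype=float)
        assert sg.auc_roc(y, s) == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 10_000)
        s = rng.normal(size=10_000)
        assert abs(sg.auc_roc(y, s) - 0.5) < 0.02

    def test_matches_all_pairs_oracle_with_ties(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]  # ensure both classes
        s = np.round(rng.normal(size=50), 1)  # coarse scores force ties
        assert sg.auc_roc(y, s) == pytest.approx(_auc_pairs_oracle(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sg.auc_roc(np.ones(10), np.arange(10.0))
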