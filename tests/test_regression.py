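"""Feature assembly, stepwise selection, LOO prediction, bootstrap stability."""

import numpy as np
import pandas as pd
import pytest

from icohnet.regression import (
    MOTOR_CHANNELS,
    Term,
    bootstrap_stability,
    build_features,
    loo_predict,
    model_formula,
    prediction_metrics,
    quadratic_scope,
    stepwise_select,
)


def _metric_long(subjects, channels, rng, pre_zero_at=None):
    rows = []
    for sid in subjects:
        for metric in ("DC", "LE", "CC"):
            for window in ("pre", "post"):
                for ch in channels:
                    v = float(rng.uniform(0.5, 1.5))
                    if pre_zero_at == (sid, metric, ch) and window == "pre":
                        v = 0.0
                    rows.append(
                        {"subject": sid, "metric": metric, "window": window, "channel": ch, "value": v}
                    )
    return pd.DataFrame(rows)


def _erd_long(subjects, channels, rng):
    return pd.DataFrame(
        [
            {"subject": sid, "channel": ch, "value": float(rng.normal(-30, 10))}
            for sid in subjects
            for ch in channels
        ]
    )


class TestBuildFeatures:
    def test_eleven_subjects_gives_11_by_72_plus_outcome(self, rng):
        subjects = [f"s{i}" for i in range(11)]
        gm = _metric_long(subjects, MOTOR_CHANNELS, rng)
        em = _erd_long(subjects, MOTOR_CHANNELS, rng)
        outcomes = pd.DataFrame({"subject": subjects, "ul_fma": rng.uniform(20, 66, 11)})
        t = build_features(gm, em, outcomes)
        assert t.shape == (11, 4 * 18 + 1)
        assert list(t.columns)[-1] == "ul_fma"

    def test_column_order_deterministic(self, rng):
        subjects = ["a", "b", "c"]
        chans = ("C3", "C4")
        gm = _metric_long(subjects, chans, rng)
        em = _erd_long(subjects, chans, rng)
        outcomes = pd.DataFrame({"subject": subjects, "ul_fma": [30.0, 40.0, 50.0]})
        t1 = build_features(gm, em, outcomes, channels=chans)
        t2 = build_features(gm.sample(frac=1, random_state=0), em, outcomes, channels=chans)
        assert list(t1.columns) == list(t2.columns)
        pd.testing.assert_frame_equal(t1, t2)

    def test_zero_pre_contrast_is_hard_error(self, rng):
        subjects = ["a", "b", "c"]
        chans = ("C3",)
        gm = _metric_long(subjects, chans, rng, pre_zero_at=("b", "DC", "C3"))
        em = _erd_long(subjects, chans, rng)
        outcomes = pd.DataFrame({"subject": subjects, "ul_fma": [30.0, 40.0, 50.0]})
        with pytest.raises(ValueError, match="b:DC\\(C3\\)"):
            build_features(gm, em, outcomes, channels=chans)

    def test_missing_channel_listed(self, rng):
        subjects = ["a", "b", "c"]
        gm = _metric_long(subjects, ("C3",), rng)
        em = _erd_long(subjects, ("C3",), rng)
        outcomes = pd.DataFrame({"subject": subjects, "ul_fma": [30.0, 40.0, 50.0]})
        with pytest.raises(ValueError, match="C4"):
            build_features(gm, em, outcomes, channels=("C3", "C4"))


class TestStepwise:
    def _table(self, rng, n=30, k=5, coef=2.0, noise=0.05):
        X = rng.standard_normal((n, k))
        y = coef * X[:, 0] + noise * rng.standard_normal(n)
        cols = {f"x{i + 1}": X[:, i] for i in range(k)}
        cols["y"] = y
        return pd.DataFrame(cols)

    def test_recovers_planted_linear_term(self, rng):
        t = self._table(rng)
        fit = stepwise_select(t, outcome="y")
        assert "x1" in [str(term) for term in fit.terms]
        row = fit.params.loc["x1"]
        ci = 1.96 * row["se"]
        assert row["coef"] - ci <= 2.0 <= row["coef"] + ci

    def test_null_outcome_selects_nothing_with_scope_corrected_alpha(self, rng):
        # min-p entry over an m-term scope inflates the family-wise rate to
        # ~1-(1-alpha)^m; at alpha/m the intercept-only model dominates under
        # the null, which checks the partial-F p-values are calibrated
        runs, picks = 100, 0
        m = 20  # quadratic scope of 5 candidates
        for _ in range(runs):
            t = self._table(rng, n=20, coef=0.0, noise=1.0)
            fit = stepwise_select(t, outcome="y", alpha_enter=0.05 / m, alpha_remove=0.05 / m)
            picks += bool(fit.terms)
        assert picks <= 0.1 * runs

    def test_zero_variance_candidate_warned_and_excluded(self, rng):
        t = self._table(rng)
        t["flat"] = 3.14
        with pytest.warns(UserWarning, match="flat"):
            fit = stepwise_select(t, outcome="y")
        assert all("flat" not in str(term) for term in fit.terms)

    def test_standardized_coefficient_identity(self, rng):
        t = self._table(rng, coef=1.5, noise=0.2)
        fit = stepwise_select(t, outcome="y")
        sy = t["y"].std(ddof=1)
        for term in fit.terms:
            row = fit.params.loc[str(term)]
            sx = np.std(term.evaluate(t), ddof=1)
            assert row["std_coef"] == pytest.approx(row["coef"] * sx / sy)

    def test_quadratic_scope_contents(self):
        terms = [str(t) for t in quadratic_scope(["a", "b"])]
        assert terms == ["a", "b", "a^2", "b^2", "a*b"]

    def test_formula_rendering(self):
        terms = [Term("lin", ("DC(C4)",)), Term("sq", ("CC(C4)",)), Term("prod", ("ERD(C2)", "ERD(C4)"))]
        assert model_formula(terms) == "y ~ 1 + DC(C4) + CC(C4)^2 + ERD(C2)*ERD(C4)"


class TestLooPredict:
    def test_noiseless_linear_data_predicts_exactly(self, rng):
        X = rng.standard_normal((12, 2))
        t = pd.DataFrame({"x1": X[:, 0], "x2": X[:, 1], "y": 3 * X[:, 0] - X[:, 1] + 5})
        res = loo_predict(t, [Term("lin", ("x1",)), Term("lin", ("x2",))], outcome="y")
        assert res.metrics["rmse_n"] == pytest.approx(0.0, abs=1e-9)
        assert res.metrics["pearson_r"] == pytest.approx(1.0)

    def test_constant_predictions_rejected(self, rng):
        t = pd.DataFrame({"x": rng.standard_normal(8), "y": np.full(8, 5.0)})
        # constant outcome -> every intercept-only fold predicts exactly 5
        with pytest.raises(ValueError, match="constant"):
            loo_predict(t, [], outcome="y")

    def test_singular_fold_named(self, rng):
        t = pd.DataFrame(
            {"x": [1.0, 0.0, 0.0, 0.0], "y": [1.0, 2.0, 3.0, 4.0]},
            index=["s1", "s2", "s3", "s4"],
        )
        with pytest.raises(np.linalg.LinAlgError, match="s1"):
            loo_predict(t, [Term("lin", ("x",))], outcome="y")


class TestPredictionMetrics:
    def test_perfect_prediction(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        m = prediction_metrics(a, a.copy())
        assert m["rmse_n"] == 0 and m["r2"] == 1 and m["pearson_r"] == 1

    def test_rmse_denominator_conventions(self, rng):
        a = rng.standard_normal(10)
        p = a + rng.standard_normal(10)
        m = prediction_metrics(a, p)
        sse = ((p - a) ** 2).sum()
        assert m["rmse_n"] == pytest.approx(np.sqrt(sse / 10))
        assert m["rmse_n1"] == pytest.approx(np.sqrt(sse / 9))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            prediction_metrics([1.0, 2.0, 3.0], [1.0, 2.0])


class TestBootstrapStability:
    def _planted_table(self, rng, n=14):
        X = rng.standard_normal((n, 4))
        y = 3.0 * X[:, 0] + 0.3 * rng.standard_normal(n)
        cols = {f"x{i + 1}": X[:, i] for i in range(4)}
        cols["y"] = y
        return pd.DataFrame(cols)

    def test_fixed_seed_reproducible(self, rng):
        t = self._planted_table(rng)
        f1 = bootstrap_stability(t, runs=40, seed=11, outcome="y")
        f2 = bootstrap_stability(t, runs=40, seed=11, outcome="y")
        pd.testing.assert_series_equal(f1, f2)

    def test_planted_feature_dominates(self, rng):
        t = self._planted_table(rng)
        freq = bootstrap_stability(t, runs=100, seed=3, outcome="y")
        assert freq.get("x1", 0.0) > 0.8
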