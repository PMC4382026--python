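import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reefbaselines import ensemble as ens


class TestEnumerateModels:
    def test_full_space_with_constraint_is_192(self):
        specs = ens.enumerate_models(ens.PREDICTORS, [("SSTL", "WV")])
        # brute-force oracle: generate every subset and filter
        oracle = [
            s
            for r in range(9)
            for s in itertools.combinations(ens.PREDICTORS, r)
            if not ("SSTL" in s and "WV" in s)
        ]
        assert len(specs) == 192
        assert len(specs) == len(oracle)
        assert set(specs) == {tuple(sorted(s)) for s in oracle}

    def test_null_only_for_empty_predictors(self):
        assert ens.enumerate_models([], []) == [()]

    def test_two_unconstrained(self):
        specs = ens.enumerate_models(["A", "B"], [])
        assert specs == [(), ("A",), ("B",), ("A", "B")]

    def test_deterministic_order(self):
        a = ens.enumerate_models(ens.PREDICTORS, [("SSTL", "WV")])
        b = ens.enumerate_models(ens.PREDICTORS, [("SSTL", "WV")])
        assert a == b
        sizes = [len(s) for s in a]
        assert sizes == sorted(sizes)

    def test_unknown_constraint_raises(self):
        with pytest.raises(ValueError):
            ens.enumerate_models(["A"], [("A", "Z")])


class TestAICc:
    def test_closed_form(self):
        assert ens.aicc(-100.0, 5, 37) == pytest.approx(210 + 60 / 31)

    def test_large_n_limit_is_aic(self):
        aic = -2 * (-50.0) + 2 * 4
        assert ens.aicc(-50.0, 4, 10**9) == pytest.approx(aic, abs=1e-6)

    def test_invalid_n_raises(self):
        with pytest.raises(ValueError):
            ens.aicc(-10.0, 5, 6)

    @given(
        ll=st.floats(-500, 0),
        k=st.floats(1, 20),
        n=st.integers(25, 500),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_independent_formula(self, ll, k, n):
        expected = -2 * ll + 2 * k + (2 * k * (k + 1)) / (n - k - 1)
        assert ens.aicc(ll, k, n) == pytest.approx(expected, rel=1e-12)


class TestAkaikeWeights:
    def test_single_model(self):
        delta, w = ens.akaike_weights([123.4])
        assert delta[0] == 0.0
        assert w[0] == pytest.approx(1.0)

    def test_two_model_closed_form(self):
        delta, w = ens.akaike_weights([100.0, 102.52])
        assert w[1] / w[0] == pytest.approx(np.exp(-1.26), rel=1e-12)
        assert w[0] == pytest.approx(1 / (1 + np.exp(-1.26)), rel=1e-12)
        assert w[0] == pytest.approx(0.779, abs=5e-4)
        assert w[1] == pytest.approx(0.221, abs=5e-4)

    def test_table_arithmetic_second_ranked_weight(self):
        # a model 2.52 AICc behind a 0.383-weight top model weighs ~0.109
        w2 = 0.383 * np.exp(-2.52 / 2)
        assert round(w2, 3) == 0.109

    def test_all_nonfinite_raises(self):
        with pytest.raises(ValueError):
            ens.akaike_weights([np.inf, np.nan])

    @given(
        st.lists(st.floats(50, 400), min_size=1, max_size=30),
    )
    @settings(max_examples=60, deadline=None)
    def test_weights_sum_to_one_deltas_nonneg(self, aiccs):
        delta, w = ens.akaike_weights(aiccs)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert (delta >= 0).all()
        assert delta.min() == 0.0
        # ranking by AICc equals ranking by weight reversed
        assert np.array_equal(
            np.argsort(np.asarray(aiccs), kind="stable"),
            np.argsort(-w, kind="stable"),
        )


class TestVariableImportance:
    def test_everywhere_is_one(self):
        specs = [("A",), ("A", "B"), ("A", "C")]
        imp = ens.variable_importance(specs, [0.5, 0.3, 0.2])
        assert imp["A"] == pytest.approx(1.0)

    def test_nowhere_is_zero(self):
        imp = ens.variable_importance([("A",), ()], [0.6, 0.4], ["A", "B"])
        assert imp["B"] == 0.0

    def test_brute_force_subset_sums(self):
        rs = np.random.default_rng(8)
        preds = list("ABCDE")
        specs = [
            tuple(p for p in preds if rs.random() < 0.5) for _ in range(10)
        ]
        w = rs.dirichlet(np.ones(10))
        imp = ens.variable_importance(specs, w, preds)
        for p in preds:
            assert imp[p] == pytest.approx(
                sum(wi for s, wi in zip(specs, w) if p in s), rel=1e-12
            )


def _gamma_table(n, seed, effect=None):
    rs = np.random.default_rng(seed)
    chl = rs.uniform(0.03, 0.21, n)
    hum = np.where(rs.random(n) < 0.5, rs.uniform(0, 6, n), 0.0)
    eta = np.full(n, np.log(40.0))
    if effect == "chl":
        eta = eta + 5.0 * (chl - 0.03)
    elif effect == "hum":
        eta = eta - 0.25 * hum
    mu = np.exp(eta)
    y = rs.gamma(40.0, mu / 40.0)
    return pd.DataFrame({"mean_total": y, "CHL": chl, "HUM": hum})


class TestFitModel:
    def test_null_model_fits_sample_mean(self):
        table = _gamma_table(30, 0)
        fit = ens.fit_model(table, "mean_total", ())
        np.testing.assert_allclose(
            fit.fit.fitted, table["mean_total"].mean(), rtol=1e-8
        )
        assert fit.k == pytest.approx(2.0)  # intercept + scale

    def test_duplicated_rows_identical_predictions_glm(self):
        table = _gamma_table(30, 1, effect="chl")
        table["AT"] = (np.arange(30) % 2).astype(float)
        doubled = pd.concat([table, table], ignore_index=True)
        f1 = ens.fit_model(table, "mean_total", ("AT",))
        f2 = ens.fit_model(doubled, "mean_total", ("AT",))
        grid = table.iloc[:5]
        np.testing.assert_allclose(
            f1.predict(grid)[0], f2.predict(grid)[0], rtol=1e-8
        )

    def test_duplicated_rows_identical_predictions_smooth(self):
        # exact duplication invariance holds when the roughness penalty is
        # scaled with n (data-driven GCV rescales it implicitly)
        table = _gamma_table(30, 1, effect="chl")
        doubled = pd.concat([table, table], ignore_index=True)
        f1 = ens.fit_model(table, "mean_total", ("CHL",), alpha=10.0)
        f2 = ens.fit_model(doubled, "mean_total", ("CHL",), alpha=20.0)
        grid = table.iloc[:5]
        np.testing.assert_allclose(
            f1.predict(grid)[0], f2.predict(grid)[0], rtol=1e-6
        )

    def test_smooth_recovery_within_pointwise_band(self):
        # single smooth CHL effect at n=200: fitted curve within the 95%
        # band of the truth at 90%+ of grid points
        table = _gamma_table(200, 2, effect="chl")
        fit = ens.fit_model(table, "mean_total", ("CHL",))
        grid = pd.DataFrame({"CHL": np.linspace(0.035, 0.205, 40)})
        mean, se = fit.predict(grid)
        truth = 40.0 * np.exp(5.0 * (grid["CHL"] - 0.03))
        inside = np.abs(mean - truth) <= 1.96 * se
        assert inside.mean() >= 0.90

    def test_nonpositive_response_raises(self):
        table = _gamma_table(30, 3)
        table.loc[0, "mean_total"] = 0.0
        with pytest.raises(ValueError):
            ens.fit_model(table, "mean_total", ("CHL",))

    def test_at_enters_linearly(self):
        table = _gamma_table(40, 4)
        table["AT"] = (np.arange(40) % 2).astype(float)
        fit = ens.fit_model(table, "mean_total", ("AT",))
        assert fit.fit.smooth_terms == ()
        assert fit.fit.linear_terms == ("AT",)


@pytest.fixture(scope="module")
def result():
    table = _gamma_table(40, 5, effect="chl")
    return ens.fit_ensemble(table, "mean_total", ["CHL", "HUM"], constraints=[])


class TestFitEnsemble:

    def test_weights_sum_to_one(self, result):
        assert sum(f.weight for f in result.fits) == pytest.approx(1.0, abs=1e-12)

    def test_deltas_ranked(self, result):
        deltas = [f.delta_aicc for f in result.fits]
        assert deltas[0] == 0.0
        assert deltas == sorted(deltas)

    def test_retained_subset(self, result):
        assert all(f.weight > 0.05 for f in result.retained)
        assert set(map(id, result.retained)) <= set(map(id, result.fits))

    def test_importance_in_unit_interval(self, result):
        assert ((result.importance >= 0) & (result.importance <= 1)).all()

    def test_table_layout(self, result):
        tab = result.table()
        for col in ("df", "adj_r2", "aicc", "delta_aicc", "weight"):
            assert col in tab.columns
        assert len(tab) == 4


class _StubFit:
    def __init__(self, yhat, se, weight):
        self.weight = weight
        self._y = np.asarray(yhat, dtype=float)
        self._se = np.asarray(se, dtype=float)
        self.spec = ("X",)

    def predict(self, data):
        return self._y.copy(), self._se.copy()


class TestModelAveragePredict:
    def test_single_model_identity(self):
        stub = _StubFit([10.0, 20.0], [1.0, 2.0], 0.4)
        mean, se = ens.model_average_predict([stub], None)
        np.testing.assert_allclose(mean, [10.0, 20.0])
        np.testing.assert_allclose(se, [1.0, 2.0])

    def test_equal_predictions_no_between_model_term(self):
        a = _StubFit([10.0], [1.0], 0.5)
        b = _StubFit([10.0], [3.0], 0.5)
        mean, se = ens.model_average_predict([a, b], None)
        assert mean[0] == pytest.approx(10.0)
        assert se[0] == pytest.approx(np.sqrt(0.5 * 1 + 0.5 * 9))

    def test_three_model_hand_formula(self):
        w = np.array([0.5, 0.3, 0.2])
        ys = np.array([10.0, 14.0, 8.0])
        ses = np.array([1.0, 2.0, 1.5])
        fits = [_StubFit([y], [s], wi) for y, s, wi in zip(ys, ses, w)]
        mean, se = ens.model_average_predict(fits, None)
        ybar = (w * ys).sum()
        var = (w * (ses**2 + (ys - ybar) ** 2)).sum()
        assert mean[0] == pytest.approx(ybar, rel=1e-12)
        assert se[0] == pytest.approx(np.sqrt(var), rel=1e-12)

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            ens.model_average_predict([], None)


class TestSmootherProfile:
    def test_reference_point_scaled_to_one(self):
        table = _gamma_table(60, 6, effect="chl")
        fit = ens.fit_model(table, "mean_total", ("CHL",))
        prof = ens.smoother_profile(fit, table, "CHL", n_grid=21)
        assert prof["scaled"].iloc[0] == pytest.approx(1.0)

    def test_human_reference_is_zero_density(self):
        table = _gamma_table(80, 7, effect="hum")
        fit = ens.fit_model(table, "mean_total", ("HUM",))
        prof = ens.smoother_profile(fit, table, "HUM", n_grid=21)
        # HUM = 0 occurs in the data, so scaled value at grid start
        # (the observed min = 0) is exactly the reference
        assert table["HUM"].min() == 0.0
        assert prof["scaled"].iloc[0] == pytest.approx(1.0)

    def test_null_effect_profile_flat_within_ci(self):
        table = _gamma_table(120, 8)
        fit = ens.fit_model(table, "mean_total", ("CHL",))
        prof = ens.smoother_profile(fit, table, "CHL", n_grid=25)
        base = table["mean_total"].mean()
        inside = (prof["lo"] <= base) & (base <= prof["hi"])
        assert inside.mean() >= 0.9

    def test_monotone_decreasing_hum_recovered(self):
        table = _gamma_table(150, 9, effect="hum")
        fit = ens.fit_model(table, "mean_total", ("HUM",))
        prof = ens.smoother_profile(fit, table, "HUM", n_grid=25)
        assert prof["scaled"].iloc[-1] < prof["scaled"].iloc[0]
        # non-increasing up to wiggle smaller than the CI half-width
        wiggle = np.diff(prof["mean"]).max()
        assert wiggle <= (1.96 * prof["se"]).max()

    def test_absent_predictor_raises(self):
        table = _gamma_table(40, 10)
        fit = ens.fit_model(table, "mean_total", ("CHL",))
        with pytest.raises(ValueError, match="absent"):
            ens.smoother_profile(fit, table, "HUM")
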