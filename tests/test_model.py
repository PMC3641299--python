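import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from degrisk.factors import FactorStack
from degrisk.geodata import Grid, GridSpec
from degrisk.model import (DegradationLogit, LogisticFit, auc_rank,
                           backward_stepwise, block_sample, compare_auc,
                           fit_logistic, odds_percent, risk_deciles,
                           significance_stars, split_calibration, validate_fit,
                           vif_screen)


def _stack(spec, layer_values):
    layers = {n: Grid(spec, v) for n, v in layer_values.items()}
    return FactorStack(spec=spec, names=list(layer_values),
                       layers=layers, kinds={n: "continuous" for n in layer_values})


def _sim_table(rng, n, beta0, beta):
    X = pd.DataFrame({f"v{k}": rng.normal(size=n) for k in range(len(beta))})
    eta = beta0 + X.to_numpy() @ np.asarray(beta)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    X["y"] = y
    return X


class TestBlockSample:
    def _grid(self, n, mask=None):
        spec = GridSpec(n, n, 0.0, n * 250.0, 250.0, "test")
        return Grid(spec, np.zeros((n, n)),
                    mask if mask is not None else np.zeros((n, n), bool))

    def test_one_row_per_window(self, rng):
        y = self._grid(9)
        stack = _stack(y.spec, {"a": rng.normal(size=(9, 9))})
        table = block_sample(y, stack, block=3, seed=1)
        assert len(table) == 9
        # exactly one sample per 3x3 window
        windows = set(zip(table["row"] // 3, table["col"] // 3))
        assert len(windows) == 9

    def test_fully_masked(self):
        y = self._grid(3, mask=np.ones((3, 3), bool))
        stack = _stack(y.spec, {"a": np.zeros((3, 3))})
        assert len(block_sample(y, stack, seed=0)) == 0

    def test_row_count_matches_window_tally(self, rng):
        mask = rng.random((12, 12)) < 0.6
        y = self._grid(12, mask=mask)
        stack = _stack(y.spec, {"a": rng.normal(size=(12, 12))})
        table = block_sample(y, stack, block=3, seed=2)
        expect = sum((~mask[i:i + 3, j:j + 3]).any()
                     for i in range(0, 12, 3) for j in range(0, 12, 3))
        assert len(table) == expect
        assert not mask[table["row"], table["col"]].any()

    def test_deterministic_under_seed(self, rng):
        y = self._grid(9)
        stack = _stack(y.spec, {"a": rng.normal(size=(9, 9))})
        t1 = block_sample(y, stack, seed=5)
        t2 = block_sample(y, stack, seed=5)
        pd.testing.assert_frame_equal(t1, t2)


class TestSplit:
    def test_equal_halves(self, rng):
        table = pd.DataFrame({"y": rng.integers(0, 2, 8112)})
        out = split_calibration(table, seed=0)
        counts = out["split"].value_counts()
        assert counts["calibration"] == 4056 and counts["validation"] == 4056

    def test_odd_count(self):
        out = split_calibration(pd.DataFrame({"y": np.zeros(5)}), seed=0)
        sizes = sorted(out["split"].value_counts())
        assert sizes == [2, 3]

    def test_deterministic(self, rng):
        table = pd.DataFrame({"y": rng.integers(0, 2, 100)})
        a = split_calibration(table, seed=3)["split"]
        b = split_calibration(table, seed=3)["split"]
        assert (a == b).all()


class TestVifScreen:
    def test_orthogonal_predictors(self):
        n = 64
        t = np.arange(n)
        table = pd.DataFrame({"a": np.sin(2 * np.pi * t / n),
                              "b": np.cos(2 * np.pi * t / n), "y": 0})
        retained, report = vif_screen(table, ["a", "b"])
        assert retained == ["a", "b"]
        assert np.allclose(report.loc[~report["removed"], "vif"], 1.0, atol=1e-9)

    def test_duplicate_removed_as_infinite(self, rng):
        x = rng.normal(size=100)
        table = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=100), "y": 0})
        retained, report = vif_screen(table, ["a", "b", "c"])
        assert len(retained) == 2 and "c" in retained
        assert np.isinf(report[report["removed"]]["vif"]).all()

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        import statsmodels.api as sm
        n, p = 300, 6
        base = rng.normal(size=(n, p))
        base[:, 3] += 0.8 * base[:, 0]  # induce some collinearity
        table = pd.DataFrame(base, columns=[f"v{k}" for k in range(p)])
        table["y"] = 0
        _, report = vif_screen(table, [f"v{k}" for k in range(p)], threshold=1e9)
        X = sm.add_constant(table[[f"v{k}" for k in range(p)]]).to_numpy()
        for k in range(p):
            expect = variance_inflation_factor(X, k + 1)
            got = float(report.loc[report["variable"] == f"v{k}", "vif"].iloc[0])
            assert got == pytest.approx(expect, abs=1e-8)


class TestLogisticFit:
    def test_intercept_only_matches_prevalence(self, rng):
        table = pd.DataFrame({"x": rng.normal(size=500),
                              "y": (rng.random(500) < 0.3).astype(int)})
        fit = fit_logistic(table, [])
        prevalence = table["y"].mean()
        fitted_p = 1.0 / (1.0 + np.exp(-fit.params["const"]))
        assert fitted_p == pytest.approx(prevalence, abs=1e-8)

    def test_null_predictors_have_moderate_z(self, rng):
        table = _sim_table(rng, 10000, beta0=-0.5, beta=[0.0, 0.0, 0.0])
        fit = fit_logistic(table, ["v0", "v1", "v2"])
        assert np.all(np.abs(fit.zvalues.drop("const")) < 4.0)

    def test_parameter_recovery_known_beta(self):
        """Wald CIs cover the generating coefficients at roughly nominal rate."""
        beta0, beta = -3.55, [1.46, 0.71, 0.40, 0.25, 0.23]
        names = [f"v{k}" for k in range(5)]
        covered = np.zeros(5, dtype=int)
        reps = 30
        for r in range(reps):
            rng = np.random.default_rng(1000 + r)
            table = _sim_table(rng, 4056, beta0, beta)
            fit = fit_logistic(table, names)
            for k, name in enumerate(names):
                lo = fit.params[name] - 1.96 * fit.bse[name]
                hi = fit.params[name] + 1.96 * fit.bse[name]
                covered[k] += int(lo <= beta[k] <= hi)
        assert np.all(covered >= int(0.85 * reps))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(pd.DataFrame({"x": [1.0, 2.0], "y": [1, 1]}), ["x"])

    def test_estimator_api_and_proba(self, rng):
        table = _sim_table(rng, 400, 0.0, [1.0])
        est = DegradationLogit().fit(table[["v0"]], table["y"])
        proba = est.predict_proba(table[["v0"]])
        assert proba.shape == (400, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert est.get_params() == {"maxiter": 100, "tol": 1e-8}


class TestBackwardStepwise:
    def test_all_noise_drops_to_intercept(self):
        rng = np.random.default_rng(42)
        table = _sim_table(rng, 2000, beta0=0.0, beta=[0.0] * 4)
        fit = backward_stepwise(table, [f"v{k}" for k in range(4)])
        assert fit.predictors == [] or all(
            fit.pvalues[p] <= 0.05 for p in fit.predictors)
        assert len(fit.drop_sequence) >= 3

    def test_strong_predictor_retained(self):
        kept = 0
        for r in range(20):
            rng = np.random.default_rng(r)
            X = pd.DataFrame({f"v{k}": rng.normal(size=800) for k in range(6)})
            eta = -0.5 + 2.0 * X["v0"]
            X["y"] = (rng.random(800) < 1 / (1 + np.exp(-eta))).astype(int)
            fit = backward_stepwise(X, [f"v{k}" for k in range(6)])
            kept += int("v0" in fit.predictors)
        assert kept == 20

    def test_alpha_one_equals_full_fit(self, rng):
        table = _sim_table(rng, 500, -0.2, [0.5, 0.0])
        full = fit_logistic(table, ["v0", "v1"])
        step = backward_stepwise(table, ["v0", "v1"], alpha_remove=1.0)
        pd.testing.assert_series_equal(full.params, step.params)


class TestAUC:
    @given(st.lists(st.tuples(st.booleans(),
                              st.integers(min_value=-5, max_value=5)),
                    min_size=4, max_size=60))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_pairwise_identity_property(self, rows):
        """Rank AUC equals the mean over positive x negative pairs for any
        finite sample with heavy ties."""
        y = np.array([float(b) for b, _ in rows])
        s = np.array([float(v) for _, v in rows])
        if y.min() == y.max():
            return
        pos, neg = s[y == 1], s[y == 0]
        brute = ((pos[:, None] > neg[None, :])
                 + 0.5 * (pos[:, None] == neg[None, :])).mean()
        assert auc_rank(y, s) == pytest.approx(brute, abs=1e-12)

    def test_pairwise_brute_force_identity(self, rng):
        y = rng.integers(0, 2, 200).astype(float)
        y[:3] = [0, 1, 0]  # both classes present
        s = np.round(rng.normal(size=200), 1)  # ties likely
        got = auc_rank(y, s)
        pos, neg = s[y == 1], s[y == 0]
        cmp = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
        assert got == cmp.mean()  # exact equality, not approx

    def test_perfect_and_tied_scores(self):
        y = np.array([0.0, 0, 1, 1])
        assert auc_rank(y, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0
        assert auc_rank(y, np.ones(4)) == 0.5


class TestCompareAUC:
    def _fit(self, names, params):
        s = pd.Series(params)
        return LogisticFit(predictors=names, params=s, bse=s, zvalues=s,
                           pvalues=s, cov=pd.DataFrame(), llf=0.0, llnull=0.0, n=0)

    def test_model_vs_itself(self, rng):
        table = pd.DataFrame({"a": rng.normal(size=100),
                              "y": rng.integers(0, 2, 100)})
        fit = self._fit(["a"], {"const": 0.0, "a": 1.0})
        res = compare_auc(fit, fit, table)
        assert res.diff == 0.0 and res.p_value == 1.0

    def test_random_vs_informative(self, rng):
        n = 400
        x = rng.normal(size=n)
        y = (x > 0).astype(float)
        table = pd.DataFrame({"good": x, "noise": rng.normal(size=n), "y": y})
        perfect = self._fit(["good"], {"const": 0.0, "good": 5.0})
        random_ = self._fit(["noise"], {"const": 0.0, "noise": 1.0})
        res = compare_auc(perfect, random_, table)
        assert res.auc_a == 1.0
        assert abs(res.auc_b - 0.5) < 0.1
        assert res.p_value < 1e-6 and res.recommended == "a"

    def test_p_value_close_to_paired_bootstrap(self):
        rng = np.random.default_rng(99)
        n = 300
        signal = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-signal))).astype(float)
        table = pd.DataFrame({"a": signal + rng.normal(0, 1.0, n),
                              "b": signal + rng.normal(0, 1.5, n), "y": y})
        fa = self._fit(["a"], {"const": 0.0, "a": 1.0})
        fb = self._fit(["b"], {"const": 0.0, "b": 1.0})
        res = compare_auc(fa, fb, table)
        # paired bootstrap of the AUC difference
        sa, sb = table["a"].to_numpy(), table["b"].to_numpy()
        diffs = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            yy = y[idx]
            if yy.min() == yy.max():
                continue
            diffs.append(auc_rank(yy, sa[idx]) - auc_rank(yy, sb[idx]))
        diffs = np.array(diffs)
        se_boot = diffs.std(ddof=1)
        from scipy import stats
        p_boot = 2 * stats.norm.sf(abs(res.diff) / se_boot)
        assert res.p_value == pytest.approx(p_boot, abs=0.02)


class TestValidateFit:
    def _fit_on(self, table, names):
        return fit_logistic(table, names)

    def test_perfect_separation_metrics(self, rng):
        x = np.concatenate([rng.uniform(-3, -1, 50), rng.uniform(1, 3, 50)])
        y = (x > 0).astype(int)
        cal = pd.DataFrame({"x": x, "y": y})
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_logistic(cal, ["x"])
        report = validate_fit(fit, cal)
        assert report.auc == 1.0 and report.pcp == 100.0

    def test_chi_square_is_lr_statistic(self, rng):
        table = _sim_table(rng, 1000, -0.5, [0.8, 0.0])
        fit = fit_logistic(table, ["v0", "v1"])
        report = validate_fit(fit, table)
        assert report.chi_square == pytest.approx(2 * (fit.llf - fit.llnull))
        assert report.chi_square_df == 2
        # PCP equals direct confusion-matrix arithmetic
        p = fit.predict_proba(table)
        correct = ((p >= 0.5).astype(int) == table["y"]).sum()
        assert report.pcp == pytest.approx(100.0 * correct / len(table))

    def test_single_class_flagged(self, rng):
        table = _sim_table(rng, 200, 0.0, [1.0])
        fit = fit_logistic(table, ["v0"])
        val = table[table["y"] == 1]
        report = validate_fit(fit, val)
        assert report.single_class and report.auc is None


class TestOdds:
    @pytest.mark.parametrize("beta,expected", [
        (0.71, 103), (0.40, 49), (0.23, 26)])
    def test_rounded_odds(self, beta, expected):
        assert round(odds_percent(beta)) == expected

    def test_reproduces_reported_odds_from_rounded_coefficient(self):
        # a 2-decimal coefficient reproduces the reported odds ratio to well
        # under 2 % relative (the residual is the rounding of beta itself)
        for beta, reported in ((1.46, 329.73), (0.71, 102.72),
                               (0.40, 48.59), (0.23, 25.96)):
            assert abs(odds_percent(beta) - reported) / reported < 0.02

    def test_exact_values(self):
        assert odds_percent(0.0) == 0.0
        assert odds_percent(-np.log(2.0)) == pytest.approx(-50.0)
        assert odds_percent(1.46) == pytest.approx(330.60, abs=0.005)

    def test_stars(self):
        assert significance_stars(0.0005) == "****"
        assert significance_stars(0.03) == "**"
        assert significance_stars(0.5) == "n.s."


class TestRiskDeciles:
    def _fit(self):
        s = pd.Series({"const": 0.0, "a": 1.0})
        return LogisticFit(predictors=["a"], params=s, bse=s, zvalues=s,
                           pvalues=s, cov=pd.DataFrame(), llf=0.0, llnull=0.0, n=0)

    def test_equal_classes_distinct_probs(self, rng):
        spec = GridSpec(10, 10, 0.0, 2500.0, 250.0, "test")
        # distinct, non-saturating linear predictors (sigmoid stays injective)
        vals = (rng.permutation(100).astype(float) / 25.0).reshape(10, 10)
        stack = _stack(spec, {"a": vals})
        risk = risk_deciles(self._fit(), stack)
        sizes = [int((risk.classes.values == c).sum()) for c in range(1, 11)]
        assert sizes == [10] * 10
        top = np.unravel_index(np.argmax(vals), vals.shape)
        assert risk.classes.values[top] == 1

    def test_tied_probabilities_use_row_col_order(self):
        spec = GridSpec(10, 10, 0.0, 2500.0, 250.0, "test")
        stack = _stack(spec, {"a": np.zeros((10, 10))})
        risk = risk_deciles(self._fit(), stack)
        # ties broken by (row, col): the first row is the top class
        assert (risk.classes.values[0, :] == 1).all()
        sizes = [int((risk.classes.values == c).sum()) for c in range(1, 11)]
        assert sizes == [10] * 10

    def test_sizes_within_one_on_ragged_n(self, rng):
        spec = GridSpec(7, 9, 0.0, 1750.0, 250.0, "test")
        mask = rng.random((7, 9)) < 0.2
        g = Grid(spec, rng.normal(size=(7, 9)), mask)
        stack = FactorStack(spec=spec, names=["a"], layers={"a": g},
                            kinds={"a": "continuous"})
        risk = risk_deciles(self._fit(), stack)
        N = int((~stack.mask).sum())
        sizes = np.array([int((risk.classes.values[~stack.mask] == c).sum())
                          for c in range(1, 11)])
        assert np.all(np.abs(sizes - N / 10.0) <= 1.0)

    def test_missing_layer_named(self):
        spec = GridSpec(2, 2, 0.0, 500.0, 250.0, "test")
        stack = _stack(spec, {"b": np.zeros((2, 2))})
        with pytest.raises(KeyError, match="a"):
            risk_deciles(self._fit(), stack)
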