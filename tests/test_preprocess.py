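import numpy as np
import pytest

from degrisk.geodata import GridSpec
from degrisk.preprocess import (DEFAULT_FLAG_WEIGHTS, MIN_POSITIVE_WEIGHT,
                                AnnualSumStack, NDVICube, SeasonWindow,
                                fill_cube_gaps, fill_gaps_linear,
                                savgol_adaptive, savgol_adaptive_cube,
                                screen_quality, seasonal_sum)


def _make_cube(rng, n_rows=4, n_cols=4, years=(2000, 2001), per_year=23):
    spec = GridSpec(n_rows, n_cols, 0.0, n_rows * 250.0, 250.0, "test")
    dates = []
    for y in years:
        for k in range(per_year):
            dates.append(np.datetime64(f"{y}-01-01") + np.timedelta64(16 * k, "D"))
    T = len(dates)
    values = rng.uniform(0.0, 0.9, (T, n_rows, n_cols))
    quality = rng.integers(0, 4, (T, n_rows, n_cols))
    return NDVICube(spec, np.array(dates, dtype="datetime64[D]"), values, quality)


class TestScreenQuality:
    def test_flag_weight_mapping(self, rng):
        cube = _make_cube(rng)
        out = screen_quality(cube)
        assert np.all(out.weights[cube.quality == 0] == 1.0)
        assert np.all(out.weights[cube.quality == 1] == 0.5)
        assert np.all(out.weights[cube.quality >= 2] == 0.0)
        assert np.isfinite(out.values[cube.quality == 0]).all()
        assert np.isnan(out.values[cube.quality == 3]).all()

    def test_masked_count_equals_zero_weight_flag_tally(self, rng):
        cube = _make_cube(rng)
        out = screen_quality(cube)
        zero_flags = sum(int((cube.quality == f).sum())
                         for f, w in DEFAULT_FLAG_WEIGHTS.items() if w == 0.0)
        assert int(np.isnan(out.values).sum()) == zero_flags

    def test_unknown_flag_named(self, rng):
        cube = _make_cube(rng)
        cube.quality[0, 0, 0] = 7
        with pytest.raises(KeyError, match="7"):
            screen_quality(cube)


class TestFillGaps:
    def test_midpoint(self):
        filled, w = fill_gaps_linear([0.0, 1.0, 2.0], [1.0, np.nan, 3.0])
        np.testing.assert_allclose(filled, [1.0, 2.0, 3.0])
        assert w[1] == MIN_POSITIVE_WEIGHT

    def test_edge_hold(self):
        filled, _ = fill_gaps_linear([0, 1, 2, 3], [np.nan, 5.0, 5.0, np.nan])
        np.testing.assert_allclose(filled, [5.0, 5.0, 5.0, 5.0])

    def test_matches_piecewise_linear_oracle(self, rng):
        t = np.arange(23, dtype=float) * 16
        y = rng.normal(size=23)
        gaps = rng.random(23) < 0.3
        y_obs = y.copy()
        y_obs[gaps] = np.nan
        if np.isfinite(y_obs).sum() < 2:
            y_obs[:2] = y[:2]
        filled, _ = fill_gaps_linear(t, y_obs)

        def oracle(tq):
            vt, vy = t[np.isfinite(y_obs)], y_obs[np.isfinite(y_obs)]
            if tq <= vt[0]:
                return vy[0]
            if tq >= vt[-1]:
                return vy[-1]
            k = np.searchsorted(vt, tq)
            if vt[k] == tq:
                return vy[k]
            f = (tq - vt[k - 1]) / (vt[k] - vt[k - 1])
            return vy[k - 1] * (1 - f) + vy[k] * f

        for k in np.flatnonzero(gaps):
            assert filled[k] == pytest.approx(oracle(t[k]), abs=1e-12)

    def test_too_few_valid_points(self):
        with pytest.raises(ValueError):
            fill_gaps_linear([0, 1, 2], [np.nan, 1.0, np.nan])

    def test_cube_fill_flags_unusable_pixels(self, rng):
        cube = _make_cube(rng, n_rows=2, n_cols=2)
        cube.weights = np.ones_like(cube.values)
        cube.values[1:, 0, 0] = np.nan
        cube.weights[1:, 0, 0] = 0.0
        filled, unusable = fill_cube_gaps(cube)
        assert unusable[0, 0] and unusable.sum() == 1
        assert np.isnan(filled.values[:, 0, 0]).all()
        assert np.isfinite(filled.values[:, 1, 1]).all()

    def test_fill_commutes_with_cropping(self, rng):
        cube = screen_quality(_make_cube(rng, n_rows=6, n_cols=6))
        full, _ = fill_cube_gaps(cube)
        sub = cube.copy()
        sub.spec = GridSpec(3, 3, 0.0, 750.0, 250.0, "test")
        sub.values = cube.values[:, :3, :3]
        sub.quality = cube.quality[:, :3, :3]
        sub.weights = cube.weights[:, :3, :3]
        cropped, _ = fill_cube_gaps(sub)
        np.testing.assert_allclose(cropped.values, full.values[:, :3, :3],
                                   equal_nan=True)


def _windowed_wls_oracle(y, w, half_window, order):
    """Direct per-point weighted polynomial fit via numpy.polyfit."""
    out = np.empty_like(y)
    T = len(y)
    for t in range(T):
        lo, hi = max(0, t - half_window), min(T, t + half_window + 1)
        x = np.arange(lo, hi, dtype=float)
        coeffs = np.polyfit(x, y[lo:hi], order, w=np.sqrt(w[lo:hi]))
        out[t] = np.polyval(coeffs, t)
    return out


class TestSavgolAdaptive:
    def test_reproduces_quadratic(self):
        t = np.arange(30, dtype=float)
        y = 0.3 + 0.02 * t - 0.001 * t ** 2
        out = savgol_adaptive(y, half_window=4, poly_order=2, envelope_iters=0)
        np.testing.assert_allclose(out, y, atol=1e-9)
        # envelope iterations change nothing when the fit is exact
        out2 = savgol_adaptive(y, half_window=4, poly_order=2, envelope_iters=3)
        np.testing.assert_allclose(out2, y, atol=1e-9)

    def test_constant_series_unchanged(self):
        y = np.full(25, 0.42)
        out = savgol_adaptive(y, envelope_iters=2)
        np.testing.assert_allclose(out, y, atol=1e-9)

    def test_matches_direct_wls_oracle(self, rng):
        t = np.arange(40, dtype=float)
        y = np.sin(t / 5.0) + rng.normal(0, 0.1, 40)
        w = rng.uniform(0.2, 1.0, 40)
        out = savgol_adaptive(y, w, half_window=4, poly_order=2, envelope_iters=0)
        oracle = _windowed_wls_oracle(y, w, 4, 2)
        np.testing.assert_allclose(out, oracle, atol=1e-8)

    def test_linear_operator_with_uniform_weights(self, rng):
        x = rng.normal(size=35)
        y = rng.normal(size=35)
        a, b = 1.7, -0.6

        def f(s):
            return savgol_adaptive(s, envelope_iters=0)

        np.testing.assert_allclose(f(a * x + b * y), a * f(x) + b * f(y), atol=1e-9)

    def test_envelope_lifts_fit_at_downweighted_point(self):
        # convex bump with one low outlier: at the outlier the envelope fit
        # rises monotonically as the decay pushes its weight toward zero
        t = np.arange(23, dtype=float)
        y = 1.0 - ((t - 11) / 12.0) ** 2
        y[8] -= 0.4
        outs = [savgol_adaptive(y, half_window=4, envelope_iters=3, weight_decay=d)[8]
                for d in (1.0, 0.5, 0.1, 0.01)]
        assert all(hi >= lo - 1e-9 for lo, hi in zip(outs[:-1], outs[1:]))
        # and the adaptive fit sits above the plain (non-envelope) fit there
        plain = savgol_adaptive(y, half_window=4, envelope_iters=0)[8]
        assert outs[-1] > plain

    def test_zero_weight_window_falls_back(self):
        y = np.linspace(0, 1, 20)
        w = np.ones(20)
        w[:9] = 0.0  # first window entirely dead
        with pytest.warns(RuntimeWarning, match="all-zero weights"):
            out = savgol_adaptive(y, w, half_window=4, envelope_iters=0)
        np.testing.assert_allclose(out, y, atol=1e-9)  # linear is reproduced anyway

    def test_window_preconditions(self):
        with pytest.raises(ValueError):
            savgol_adaptive(np.ones(30), half_window=1, poly_order=5)
        with pytest.raises(ValueError):
            savgol_adaptive(np.ones(5), half_window=4)


class TestSeasonalSum:
    def test_thirteen_half_composites(self, rng):
        cube = _make_cube(rng, years=(2005,))
        cube.values[:] = 0.5
        window = SeasonWindow()
        n_in = int(window.contains(cube.dates).sum())
        assert n_in == 13
        stack = seasonal_sum(cube, window, [2005])
        np.testing.assert_allclose(stack.values[0], 6.5)

    def test_membership_by_start_date(self):
        window = SeasonWindow()
        dates = np.array(["2005-03-20", "2005-04-06", "2005-10-31", "2005-11-01"],
                         dtype="datetime64[D]")
        np.testing.assert_array_equal(window.contains(dates),
                                      [False, True, True, False])

    def test_matches_independent_masked_sum(self, rng):
        cube = _make_cube(rng, years=(2000, 2001, 2002))
        window = SeasonWindow()
        stack = seasonal_sum(cube, window, [2000, 2001, 2002])
        import pandas as pd
        years = pd.DatetimeIndex(cube.dates).year
        for yi, year in enumerate((2000, 2001, 2002)):
            sel = window.contains(cube.dates) & (years == year)
            expect = cube.values[sel].sum(axis=0)
            np.testing.assert_allclose(stack.values[yi], expect)

    def test_additive_over_window_partition(self, rng):
        cube = _make_cube(rng, years=(2001,))
        whole = seasonal_sum(cube, SeasonWindow((4, 1), (10, 31)), [2001])
        first = seasonal_sum(cube, SeasonWindow((4, 1), (7, 15)), [2001])
        second = seasonal_sum(cube, SeasonWindow((7, 16), (10, 31)), [2001])
        np.testing.assert_allclose(first.values + second.values, whole.values)

    def test_empty_year_reported(self, rng):
        cube = _make_cube(rng, years=(2000,))
        with pytest.raises(ValueError, match="2001"):
            seasonal_sum(cube, SeasonWindow(), [2000, 2001])
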