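import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from paleodiv import (
    bca_bootstrap,
    correlate_series,
    first_difference,
    generalized_difference,
    spearman,
    uniform_timescale,
)
from paleodiv.errors import AlignmentError
from paleodiv.stats import _bca_interval


class TestFirstDifference:
    def test_examples(self):
        np.testing.assert_array_equal(first_difference([1, 4, 9]), [3, 5])
        np.testing.assert_array_equal(first_difference([7, 7, 7, 7]), [0, 0, 0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            first_difference([1.0])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=40))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_matches_pairwise_subtraction(self, values):
        got = first_difference(values)
        expected = [values[i + 1] - values[i] for i in range(len(values) - 1)]
        np.testing.assert_allclose(got, expected)


class TestGeneralizedDifference:
    def test_exact_linear_series_annihilated(self):
        t = np.arange(10.0)
        s = 2.0 * t + 3.0
        np.testing.assert_allclose(generalized_difference(s, t), 0.0, atol=1e-10)

    def test_invariant_to_affine_trend(self):
        rng = np.random.default_rng(1)
        t = np.linspace(0, 50, 20)
        s = rng.normal(size=20)
        base = generalized_difference(s, t)
        shifted = generalized_difference(s + 4.2 * t - 17.0, t)
        np.testing.assert_allclose(base, shifted, atol=1e-9)

    def test_quadratic_against_closed_form_ols(self):
        """s = t^2 on t = 1..5: OLS slope 6, intercept -7, residuals
        [2, -1, -2, -1, 2] → differences [-3, -1, 1, 3]."""
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        got = generalized_difference(t**2, t)
        np.testing.assert_allclose(got, [-3.0, -1.0, 1.0, 3.0], atol=1e-9)

    def test_degenerate_times_rejected(self):
        with pytest.raises(ValueError):
            generalized_difference([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)
        x = np.array([0.1, 1.0, 2.0, 5.0])
        assert spearman(x, np.exp(x)) == pytest.approx(1.0)

    def test_ties_match_midrank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 8.0])
        y = np.array([3.0, 1.0, 4.0, 4.0, 2.0, 6.0, 6.0, 7.0])

        def midranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v), dtype=float)
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks

        rx, ry = midranks(x), midranks(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_constant_input_undefined(self):
        assert np.isnan(spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]))


class TestBcaBootstrap:
    def test_degenerate_perfect_correlation(self):
        x = np.arange(10.0)
        result = bca_bootstrap(x, x, n_boot=999, seed=0)
        assert result.rho == 1.0
        assert result.ci95 == (1.0, 1.0) and result.ci99 == (1.0, 1.0)
        assert result.significant95 and result.significant99

    def test_preconditions(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError):
            bca_bootstrap(x, x, n_boot=10, seed=0)
        with pytest.raises(ValueError):
            bca_bootstrap(x[:4], x[:4], n_boot=999, seed=0)

    def test_bit_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=30), rng.normal(size=30)
        a = bca_bootstrap(x, y, n_boot=999, seed=99)
        b = bca_bootstrap(x, y, n_boot=999, seed=99)
        assert a.rho == b.rho and a.ci95 == b.ci95 and a.ci99 == b.ci99
        assert a.dropped_replicates == b.dropped_replicates

    def test_ci99_contains_ci95(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        r = bca_bootstrap(x, y, n_boot=1999, seed=5)
        assert r.ci99[0] <= r.ci95[0] and r.ci95[1] <= r.ci99[1]
        assert -1.0 <= r.ci99[0] <= r.ci99[1] <= 1.0

    def test_reduces_to_percentile_without_corrections(self):
        reps = np.sort(np.random.default_rng(6).normal(size=5000))
        lo, hi = _bca_interval(reps, 0.0, z0=0.0, accel=0.0, level=95.0)
        assert lo == pytest.approx(np.quantile(reps, 0.025), abs=1e-12)
        assert hi == pytest.approx(np.quantile(reps, 0.975), abs=1e-12)

    def test_against_scipy_bca(self):
        """Independent check of the BCa machinery against scipy's implementation."""
        rng = np.random.default_rng(12)
        x = rng.normal(size=40)
        y = 0.6 * x + rng.normal(size=40)
        ours = bca_bootstrap(x, y, n_boot=4999, seed=7)
        ref = sps.bootstrap(
            (x, y),
            lambda a, b: sps.spearmanr(a, b).statistic,
            paired=True,
            vectorized=False,
            n_resamples=4999,
            method="BCa",
            confidence_level=0.95,
            random_state=np.random.default_rng(7),
        )
        assert ours.ci95[0] == pytest.approx(ref.confidence_interval.low, abs=0.05)
        assert ours.ci95[1] == pytest.approx(ref.confidence_interval.high, abs=0.05)

    def test_null_coverage_on_independent_noise(self):
        """CI95 should bracket zero for most independent-noise draws."""
        rng = np.random.default_rng(2024)
        hits = 0
        repeats = 40
        for _ in range(repeats):
            x, y = rng.normal(size=50), rng.normal(size=50)
            r = bca_bootstrap(x, y, n_boot=999, seed=int(rng.integers(2**31)))
            hits += r.ci95[0] <= 0.0 <= r.ci95[1]
        assert hits / repeats >= 0.85


@pytest.fixture(scope="module")
def ts30():
    return uniform_timescale(30, 5.0)


class TestCorrelateSeries:

    def _series(self, ts, values):
        return pd.Series(values, index=[s.name for s in ts.stages[: len(values)]])

    def test_identical_series_raw(self, ts30):
        x = self._series(ts30, np.arange(30.0) + 1)
        r = correlate_series(x, x, ts30, window=("S03", "S28"), mode="raw",
                             n_boot=999, seed=1)
        assert r.rho == pytest.approx(1.0)

    def test_window_excluding_all_data_errors(self, ts30):
        x = self._series(ts30, np.arange(10.0))
        y = self._series(ts30, np.full(10, np.nan))
        with pytest.raises(AlignmentError):
            correlate_series(x, y, ts30, window=("S01", "S10"), mode="raw",
                             n_boot=999, seed=1)

    def test_common_trend_with_independent_noise(self, ts30):
        """Shared trend inflates the raw correlation; differencing removes it."""
        rng = np.random.default_rng(55)
        trend = np.linspace(0, 60, 30)
        x = self._series(ts30, trend + rng.normal(0, 3, 30))
        y = self._series(ts30, trend + rng.normal(0, 3, 30))
        raw = correlate_series(x, y, ts30, window=("S01", "S30"), mode="raw",
                               n_boot=999, seed=2)
        diff = correlate_series(x, y, ts30, window=("S01", "S30"), mode="first_diff",
                                n_boot=999, seed=2)
        assert raw.rho > 0.8
        assert abs(diff.rho) < 0.45

    def test_mode_shortens_series_by_one(self, ts30):
        x = self._series(ts30, np.random.default_rng(0).normal(size=30))
        y = self._series(ts30, np.random.default_rng(1).normal(size=30))
        raw = correlate_series(x, y, ts30, window=("S01", "S30"), mode="raw",
                               n_boot=999, seed=3)
        fd = correlate_series(x, y, ts30, window=("S01", "S30"), mode="first_diff",
                              n_boot=999, seed=3)
        assert fd.n == raw.n - 1

    def test_generalized_diff_time_axis_choices(self, ts30):
        rng = np.random.default_rng(77)
        x = self._series(ts30, rng.normal(size=30).cumsum())
        y = self._series(ts30, rng.normal(size=30).cumsum())
        by_age = correlate_series(x, y, ts30, window=("S01", "S30"),
                                  mode="generalized_diff", time_axis="midpoint",
                                  n_boot=999, seed=4)
        by_index = correlate_series(x, y, ts30, window=("S01", "S30"),
                                    mode="generalized_diff", time_axis="index",
                                    n_boot=999, seed=4)
        # uniform stages: midpoint age is an affine function of index, so the
        # two regressions leave identical residual differences
        assert by_age.rho == pytest.approx(by_index.rho, abs=1e-12)
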