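"""Cross-dating statistics, detrending, robust means, EPS/Rbar."""

import numpy as np
import pytest

from dendrotrend.chronology import (
    ChronologyError,
    IndexSeries,
    biweight_mean,
    build_chronology,
    crossdate_stats,
    detrend,
    eps_from_rbar,
    normalize_p2yrsl,
    rbar_and_eps,
    spline32_fit,
)
from dendrotrend.ringio import RingSeries


def _series(widths, first_year=1900, sid="S1"):
    return RingSeries(sid, sid, first_year, np.asarray(widths, float))


class TestP2YrsL:
    def test_constant_series_maps_to_zero(self):
        out = normalize_p2yrsl(_series([2.0] * 10))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_direct_formula(self):
        out = normalize_p2yrsl(_series([1.0, 3.0]))
        assert out.values[0] == pytest.approx(np.log(2 * 3 / 4))

    def test_output_shorter_by_one(self):
        out = normalize_p2yrsl(_series([1, 2, 3, 4, 5]))
        assert len(out) == 4
        assert out.first_year == 1901

    def test_zero_width_rejected(self):
        with pytest.raises(ChronologyError):
            normalize_p2yrsl(_series([1.0, 0.0, 2.0]))


class TestCrossdate:
    def test_identical_series_passes_with_sentinel_t(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=50)
        a = IndexSeries("a", 1950, v)
        b = IndexSeries("b", 1950, v.copy())
        r, t, ok = crossdate_stats(a, b)
        assert r == pytest.approx(1.0)
        assert t >= 1e6
        assert ok

    def test_exact_threshold_r_fails(self):
        """r = 0.32 exactly does not pass (strict inequality)."""
        n = 50
        rng = np.random.default_rng(1)
        u = rng.normal(size=n)
        u = (u - u.mean()) / np.linalg.norm(u - u.mean())
        w = rng.normal(size=n)
        w = w - w.mean() - (u @ (w - w.mean())) * u
        w /= np.linalg.norm(w)
        y = 0.32 * u + np.sqrt(1 - 0.32**2) * w
        r, t, ok = crossdate_stats(IndexSeries("a", 0, u),
                                   IndexSeries("b", 0, y))
        assert r == pytest.approx(0.32, abs=1e-9)
        assert not ok

    def test_antiphase_fails(self):
        v = np.array([1.0, -1.0] * 6)
        r, t, ok = crossdate_stats(IndexSeries("a", 0, v),
                                   IndexSeries("b", 0, -v))
        assert r < 0 and not ok

    def test_short_overlap_rejected(self):
        a = IndexSeries("a", 0, np.arange(5.0))
        b = IndexSeries("b", 0, np.arange(5.0))
        with pytest.raises(ChronologyError, match="overlap"):
            crossdate_stats(a, b)


class TestDetrend:
    def test_mean_line_exact(self):
        out = detrend(_series([2.0, 4.0, 6.0]), "mean_line")
        np.testing.assert_allclose(out.values, [0.5, 1.0, 1.5])

    def test_constant_gives_ones(self):
        for method in ("mean_line", "spline32"):
            out = detrend(_series([3.0] * 40), method)
            np.testing.assert_allclose(out.values, 1.0, atol=1e-8)

    def test_spline_frequency_response(self):
        """The spline passes ~50 % at 32 yr, less below, more above."""
        n = 600
        x = np.arange(n)

        def response(wavelength):
            y = np.sin(2 * np.pi * x / wavelength)
            fit = spline32_fit(y)
            core = slice(100, -100)
            return fit[core] @ y[core] / (y[core] @ y[core])

        assert response(32) == pytest.approx(0.5, abs=0.02)
        assert response(8) < 0.1
        assert response(64) > 0.9

    def test_spline_attenuates_low_frequency_trend_more(self):
        """Dividing by the spline removes a 64-yr cycle but keeps an 8-yr one."""
        n = 256
        t = np.arange(n)
        slow = _series(10 + 3 * np.sin(2 * np.pi * t / 64))
        fast = _series(10 + 3 * np.sin(2 * np.pi * t / 8))
        res_slow = detrend(slow, "spline32").values - 1
        res_fast = detrend(fast, "spline32").values - 1
        assert np.std(res_slow) < 0.3 * np.std(res_fast)

    def test_non_positive_spline_fit_reported(self):
        widths = np.concatenate([np.full(30, 5.0), np.full(30, 0.001)])
        s = RingSeries("S1", "S1", 2000, widths)
        # mean-line stays positive; engineered crash can push spline negative
        try:
            detrend(s, "spline32")
        except ChronologyError as exc:
            assert "year" in str(exc)


class TestBiweight:
    def test_symmetric_triple(self):
        assert biweight_mean([0.8, 1.0, 1.2]) == pytest.approx(1.0)

    def test_outlier_resistance(self):
        """One wild value barely moves the estimate (mean would be 20.8)."""
        assert biweight_mean([1, 1, 1, 1, 100]) == pytest.approx(1.0, abs=0.01)

    def test_singleton_identity(self):
        assert biweight_mean([3.7]) == 3.7

    def test_between_min_and_max(self):
        rng = np.random.default_rng(5)
        x = rng.lognormal(size=25)
        m = biweight_mean(x)
        assert x.min() <= m <= x.max()


class TestEpsRbar:
    def test_eps_closed_form_limits(self):
        assert eps_from_rbar(10, 0.0) == 0.0
        assert eps_from_rbar(1, 1.0) == 1.0

    @pytest.mark.parametrize("n", [5, 10, 23])
    def test_eps_monotone_in_rbar_and_n(self, n):
        grid = np.linspace(0.05, 0.95, 10)
        eps = [eps_from_rbar(n, r) for r in grid]
        assert np.all(np.diff(eps) > 0)
        assert eps_from_rbar(n + 5, 0.5) > eps_from_rbar(n, 0.5)

    def test_rbar_recovers_common_signal_share(self):
        """Series = signal + unit noise -> rbar ~ var(signal)/(var(signal)+1),
        using the realized signal variance of the draw."""
        rng = np.random.default_rng(7)
        signal = rng.normal(size=120)
        series = [
            IndexSeries(f"s{i}", 1900, signal + rng.normal(size=120))
            for i in range(12)
        ]
        stats = rbar_and_eps(series, (1900, 2019))
        s2 = signal.var(ddof=1)
        assert stats.rbar == pytest.approx(s2 / (s2 + 1), abs=0.07)
        assert stats.n_trees == pytest.approx(12)

    def test_insufficient_overlap_rejected(self):
        a = IndexSeries("a", 1900, np.random.default_rng(0).normal(size=20))
        b = IndexSeries("b", 1950, np.random.default_rng(1).normal(size=20))
        with pytest.raises(ChronologyError):
            rbar_and_eps([a, b], (1900, 1969))


class TestBuildChronology:
    def test_identity_on_copies(self):
        v = np.array([1.0, 2.0, 3.0, 2.0])
        series = [IndexSeries(f"s{i}", 2000, v.copy()) for i in range(4)]
        ch = build_chronology(series)
        np.testing.assert_allclose(ch.values, v)

    def test_betweenness(self):
        lo = IndexSeries("lo", 2000, np.full(10, 1.0))
        hi = IndexSeries("hi", 2000, np.full(10, 3.0))
        ch = build_chronology([lo, hi])
        assert np.all(ch.values >= 1.0) and np.all(ch.values <= 3.0)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        series = [IndexSeries(f"s{i}", 2000, rng.normal(size=30))
                  for i in range(6)]
        a = build_chronology(series)
        b = build_chronology(series[::-1])
        np.testing.assert_allclose(a.values, b.values)

    def test_noise_averaging_beats_single_series(self):
        """The chronology tracks a common signal better than any one series."""
        rng = np.random.default_rng(11)
        signal = rng.normal(size=150)
        series = [IndexSeries(f"s{i}", 1850, signal + rng.normal(size=150))
                  for i in range(10)]
        ch = build_chronology(series)
        r_chron = np.corrcoef(ch.values, signal)[0, 1]
        r_each = [np.corrcoef(s.values, signal)[0, 1] for s in series]
        assert r_chron > max(r_each)

    def test_sample_depth_and_reliable_span(self):
        series = [IndexSeries(f"s{i}", 2000 + i, np.ones(10 - i))
                  for i in range(6)]
        ch = build_chronology(series, min_depth=5)
        assert ch.first_year == 2000
        assert ch.sample_depth[0] == 1
        assert ch.first_reliable_year == 2004
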