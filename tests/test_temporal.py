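"""Episode selection, lagged cross-correlation, prevalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from remaperiodic.simulate import synth_coupled_series
from remaperiodic.temporal import (
    bayesian_prevalence,
    cross_correlate,
    episode_effect_size,
    pool_episode_correlations,
    rank_with_ties,
    select_episodes,
)


class TestSelectEpisodes:
    def test_long_run_included(self):
        hyp = np.array(["W"] * 4 + ["R"] * 24 + ["W"] * 4)  # 12 min of REM
        assert select_episodes(hyp) == [(120.0, 840.0)]

    def test_short_run_excluded(self):
        hyp = np.array(["R"] * 18)  # 9 min
        assert select_episodes(hyp) == []

    def test_exactly_ten_minutes_excluded(self):
        hyp = np.array(["R"] * 20)  # 600 s is not *longer than* 10 min
        assert select_episodes(hyp) == []

    def test_interrupted_run_splits(self):
        hyp = np.array(["R"] * 22 + ["N2"] + ["R"] * 22)
        eps = select_episodes(hyp)
        assert len(eps) == 2
        assert eps[0][1] <= eps[1][0]

    def test_empty_hypnogram_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_episodes(np.array([]))


class TestRanks:
    @pytest.mark.parametrize(
        "x, expected",
        [
            ([10, 20, 30], [1, 2, 3]),
            ([5, 5, 9], [1.5, 1.5, 3]),
            ([7, 7, 7, 7], [2.5, 2.5, 2.5, 2.5]),
        ],
    )
    def test_mid_ranks(self, x, expected):
        np.testing.assert_allclose(rank_with_ties(np.array(x)), expected)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            rank_with_ties(np.array([1.0, np.nan]))


class TestCrossCorrelate:
    def test_identical_series_r1_at_lag0(self, rng):
        x = rng.standard_normal(100)
        res = cross_correlate(x, x)
        i0 = np.flatnonzero(res.lags == 0)[0]
        assert res.r[i0] == pytest.approx(1.0)
        assert res.lags.size == 151

    def test_slope_leading_peaks_at_negative_lag(self, rng):
        """EM series delayed by 2 epochs relative to slope: slope leads,
        so the peak sits at lag -8 s under the plotting convention."""
        slope = rng.standard_normal(120)
        em = np.roll(slope, 2)
        em[:2] = rng.standard_normal(2)
        res = cross_correlate(slope, em)
        assert res.lags[np.nanargmax(np.abs(res.r))] == -8.0

    def test_antisymmetry(self, rng):
        x = rng.standard_normal(80)
        y = rng.standard_normal(80)
        ab = cross_correlate(x, y)
        ba = cross_correlate(y, x)
        np.testing.assert_allclose(ab.r, ba.r[::-1], atol=1e-12, equal_nan=True)

    def test_extreme_lags_missing(self, rng):
        x = rng.standard_normal(60)
        res = cross_correlate(x, rng.standard_normal(60))
        assert np.isnan(res.r[np.abs(res.lags) > 55 * 4]).all()
        assert np.isfinite(res.r[np.abs(res.lags) <= 50 * 4]).all()

    def test_fisher_z_definition(self, rng):
        x = rng.standard_normal(100)
        res = cross_correlate(x, 0.5 * x + rng.standard_normal(100))
        ok = np.isfinite(res.r)
        np.testing.assert_allclose(res.z[ok], np.arctanh(res.r[ok]), atol=1e-9)

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValueError, match="short"):
            cross_correlate(np.arange(8.0), np.arange(8.0))

    def test_null_significance_rate_near_alpha(self):
        rates = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            res = cross_correlate(r.standard_normal(250), r.standard_normal(250))
            ok = np.isfinite(res.r)
            rates.append(res.significant[ok].mean())
        assert np.mean(rates) == pytest.approx(0.05, abs=0.02)


class TestPooling:
    def test_single_episode_identity(self, rng):
        res = cross_correlate(rng.standard_normal(50), rng.standard_normal(50))
        pooled = pool_episode_correlations([res])
        np.testing.assert_allclose(pooled["mean_z"], res.z, equal_nan=True)

    def test_opposite_episodes_cancel(self, rng):
        x, y = rng.standard_normal(60), rng.standard_normal(60)
        a = cross_correlate(x, y)
        b = cross_correlate(x, -y)
        pooled = pool_episode_correlations([a, b])
        ok = np.isfinite(pooled["mean_z"])
        np.testing.assert_allclose(pooled["mean_z"][ok], 0.0, atol=1e-9)

    def test_coupled_episodes_peak_at_generative_lag(self):
        results = [
            cross_correlate(*synth_coupled_series(150, lag_epochs=1, seed=s))
            for s in range(200, 215)
        ]
        pooled = pool_episode_correlations(results)
        assert pooled["lags"][np.nanargmax(np.abs(pooled["mean_z"]))] == 4.0


class TestEffectSize:
    def _mock(self, sig, r=0.5):
        res = cross_correlate(np.arange(20.0), np.arange(20.0) * 0 + np.random.default_rng(0).standard_normal(20))
        i0 = np.flatnonzero(res.lags == 0)[0]
        res.significant[:] = False
        res.significant[i0] = sig
        res.r[i0] = r
        return res

    def test_fraction(self):
        results = [self._mock(True)] * 29 + [self._mock(False)] * 11
        assert episode_effect_size(results) == pytest.approx(0.725)

    def test_sign_filter(self):
        results = [self._mock(True, r=0.5), self._mock(True, r=-0.5)]
        assert episode_effect_size(results, sign="negative") == 0.5
        assert episode_effect_size(results, sign="positive") == 0.5

    def test_empty(self):
        assert episode_effect_size([]) == 0.0


class TestPrevalence:
    def test_all_significant_gives_map_one(self):
        assert bayesian_prevalence(40, 40).map_estimate == pytest.approx(1.0)

    def test_rate_at_alpha_gives_map_zero(self):
        assert bayesian_prevalence(2, 40).map_estimate == pytest.approx(0.0)

    def test_closed_form_example(self):
        est = bayesian_prevalence(12, 40)
        assert est.map_estimate == pytest.approx((0.3 - 0.05) / 0.95, abs=1e-3)

    def test_hpdi_contains_map(self):
        est = bayesian_prevalence(12, 40)
        assert est.hpdi[0] <= est.map_estimate <= est.hpdi[1]

    def test_hpdi_narrows_with_n(self):
        wide = bayesian_prevalence(5, 10)
        narrow = bayesian_prevalence(50, 100)
        assert (narrow.hpdi[1] - narrow.hpdi[0]) < (wide.hpdi[1] - wide.hpdi[0])

    @settings(deadline=None, max_examples=60)
    @given(st.integers(0, 100).flatmap(
        lambda n: st.tuples(st.just(n), st.integers(0, n))))
    def test_map_matches_closed_form(self, nk):
        n, k = nk
        if n == 0:
            return
        est = bayesian_prevalence(k, n)
        expected = max(0.0, (k / n - 0.05) / 0.95)
        assert est.map_estimate == pytest.approx(expected, abs=1e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bayesian_prevalence(5, 4)
        with pytest.raises(ValueError):
            bayesian_prevalence(1, 4, alpha=1.5)
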