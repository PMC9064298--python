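"""Displacement-distribution estimators: closed-form oracles and invariances."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mtgrowth.trace_stats import (TipTrace, analyze_batch, analyze_trace,
                                  concentration_series_fit, displacement_stats,
                                  downsample_trace, fit_growth_rate,
                                  fit_growth_variance, fluctuation_curve)

T = 0.1  # s, frame exposure


def make_trace(lengths, conc=None):
    return TipTrace(times=np.arange(len(lengths)) * T, lengths=lengths,
                    concentration=conc)


class TestDownsample:
    def test_window_one_is_identity(self):
        tr = make_trace(np.arange(50.0))
        (out,) = downsample_trace(tr, 1)
        assert np.array_equal(out, tr.lengths)

    def test_constant_trace(self):
        tr = make_trace(np.full(100, 7.5))
        for phase in downsample_trace(tr, 8):
            assert np.allclose(phase, 7.5)

    def test_ramp_block_means_at_block_centers(self):
        v = 5.0
        tr = make_trace(v * np.arange(200) * T)
        n = 10
        for p, phase in enumerate(downsample_trace(tr, n)):
            centers = (p + (n - 1) / 2.0 + n * np.arange(phase.size)) * T
            assert np.allclose(phase, v * centers)

    def test_phase_count_and_short_trace(self):
        tr = make_trace(np.arange(40.0))
        assert len(downsample_trace(tr, 6)) == 5
        with pytest.raises(ValueError):
            downsample_trace(tr, 25)


class TestDisplacementStats:
    def test_ramp_mean_and_zero_variance(self):
        v = 5.0
        tr = make_trace(v * np.arange(400) * T)
        for n in (2, 5, 10):
            s = displacement_stats(tr, n)
            assert s.mean == pytest.approx(v * n * T)
            assert s.variance == pytest.approx(0.0, abs=1e-18)
            assert s.dt == pytest.approx(n * T)

    def test_iid_noise_variance_falls_as_2_sigma2_over_n(self, rng):
        sigma = 4.0
        tr = make_trace(rng.normal(0, sigma, 60_000))
        for n in (5, 20):
            s = displacement_stats(tr, n)
            assert s.mean == pytest.approx(0.0, abs=0.3)
            assert s.variance == pytest.approx(2 * sigma**2 / n, rel=0.1)

    def test_brownian_block_mean_variance_law(self, rng):
        # adjacent-block-mean differences of a Brownian path: the pooled
        # variance at lag n*T is (2n^2+1)/(3n^2) * 2 D (n T)
        D = 10.0
        x = np.cumsum(rng.normal(0, np.sqrt(2 * D * T), 400_000))
        tr = make_trace(x)
        for n in (20, 100):
            s = displacement_stats(tr, n)
            expected = (2 * n * n + 1) / (3.0 * n * n) * 2 * D * n * T
            assert s.variance == pytest.approx(expected, rel=0.08)

    def test_insufficient_displacements(self):
        tr = make_trace(np.arange(30.0))
        with pytest.raises(ValueError):
            displacement_stats(tr, 14)


class TestFits:
    def test_ramp_growth_rate_exact(self):
        tr = make_trace(5.0 * np.arange(1200) * T)
        assert fit_growth_rate(fluctuation_curve(tr)) == pytest.approx(5.0)

    def test_zero_trace(self):
        tr = make_trace(np.zeros(1200))
        assert fit_growth_rate(fluctuation_curve(tr)) == pytest.approx(0.0)

    def test_variance_fit_recovers_own_functional_form(self):
        # synthesize the model's own curve: var = 2 D dt + A/dt
        import pandas as pd
        D, sigma_i = 10.0, 3.0
        n = np.arange(2, 301)
        dt = n * T
        A = 2 * sigma_i**2 * T
        curve = pd.DataFrame({"n": n, "dt": dt,
                              "mean": 5.0 * dt,
                              "variance": 2 * D * dt + A / dt,
                              "count": 1000})
        res = fit_growth_variance(curve)
        assert res.growth_variance == pytest.approx(D, rel=1e-3)
        assert res.sigma_i == pytest.approx(sigma_i, rel=0.02)
        assert res.r_squared > 0.999

    def test_pure_noise_trace_gives_zero_D(self, rng):
        tr = make_trace(rng.normal(0, 3.0, 6000))
        res = analyze_trace(tr)
        assert res.growth_variance == pytest.approx(0.0, abs=0.05)
        assert res.sigma_i == pytest.approx(3.0, rel=0.15)

    def test_exact_ramp_full_pipeline(self):
        res = analyze_trace(make_trace(5.0 * np.arange(2000) * T))
        assert res.growth_rate == pytest.approx(5.0)
        assert res.growth_variance == pytest.approx(0.0, abs=1e-12)
        assert res.sigma_i == pytest.approx(0.0, abs=1e-6)

    def test_short_episode_rejected(self):
        with pytest.raises(ValueError):
            analyze_trace(make_trace(np.arange(500.0)))   # 50 s < 90 s

    def test_noise_offset_helper(self):
        res = analyze_trace(make_trace(5.0 * np.arange(2000) * T))
        assert res.variance_with_noise_offset() == pytest.approx(0.97)


class TestInvariances:
    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.floats(-50, 50), st.floats(-3, 3))
    def test_offset_and_tilt_invariance(self, offset, extra_slope):
        rng = np.random.default_rng(7)
        base = 4.0 * np.arange(1500) * T + rng.normal(0, 2.0, 1500)
        r0 = analyze_trace(make_trace(base))
        r1 = analyze_trace(make_trace(base + offset
                                      + extra_slope * np.arange(1500) * T))
        assert r1.growth_rate == pytest.approx(r0.growth_rate + extra_slope,
                                               abs=1e-6)
        assert r1.growth_variance == pytest.approx(r0.growth_variance, abs=1e-9)
        assert r1.sigma_i == pytest.approx(r0.sigma_i, abs=1e-9)

    def test_additive_noise_separation(self, rng):
        # extra iid frame noise must load on sigma_i, not on D
        D = 8.0
        w = np.cumsum(rng.normal(0, np.sqrt(2 * D * T), 9000))
        clean = 5.0 * np.arange(9000) * T + w
        noisy = clean + rng.normal(0, 5.0, 9000)
        r_clean = analyze_trace(make_trace(clean))
        r_noisy = analyze_trace(make_trace(noisy))
        assert abs(r_noisy.growth_variance - r_clean.growth_variance) < 1.5
        assert r_noisy.sigma_i > r_clean.sigma_i + 3.0


class TestSeriesFit:
    def _table(self, concs, rates, n_eps=6, spread=0.0, rng=None):
        import pandas as pd
        rows = []
        for c, r in zip(concs, rates):
            for e in range(n_eps):
                jitter = 0.0 if rng is None else rng.normal(0, spread)
                rows.append({"concentration": c, "growth_rate": r + jitter})
        return pd.DataFrame(rows)

    def test_exact_line(self, rng):
        concs = [0.5, 0.7, 1.1, 1.3, 1.5]
        rates = [3.1 * (c - 0.05) for c in concs]
        tab = self._table(concs, rates, spread=1e-9, rng=rng)
        fit = concentration_series_fit(tab)
        assert fit.slope == pytest.approx(3.1, rel=1e-4)
        assert fit.x_intercept == pytest.approx(0.05, abs=1e-3)

    def test_order_invariance(self, rng):
        concs = [1.5, 0.5, 1.1, 0.7, 1.3]
        rates = [2.0 * c + 0.3 for c in concs]
        tab = self._table(concs, rates, spread=0.05, rng=rng)
        f1 = concentration_series_fit(tab)
        f2 = concentration_series_fit(tab.sample(frac=1.0, random_state=1))
        assert f1.slope == pytest.approx(f2.slope)
        assert f1.x_intercept == pytest.approx(f2.x_intercept)

    def test_weights_are_inverse_sem_not_squared(self, rng):
        # heteroscedastic series where 1/SEM and 1/SEM^2 give different slopes
        concs = [1.0, 2.0, 3.0]
        tab = self._table(concs, [1.0, 2.1, 2.8], n_eps=8, spread=0.05, rng=rng)
        # inflate the scatter of the last concentration only
        noise = rng.normal(0, 1.0, 8)
        tab.loc[tab.concentration == 3.0, "growth_rate"] += noise
        fit = concentration_series_fit(tab)
        s = fit.summary
        w = 1.0 / s["sem"].to_numpy()
        x, y = s["concentration"].to_numpy(), s["mean"].to_numpy()
        sw = np.sqrt(w)
        A = np.stack([np.ones_like(x), x], 1) * sw[:, None]
        a, b = np.linalg.lstsq(A, y * sw, rcond=None)[0]
        assert fit.slope == pytest.approx(b)
        assert fit.y_intercept == pytest.approx(a)

    def test_zero_sem_falls_back_unweighted(self):
        tab = self._table([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], n_eps=1)
        fit = concentration_series_fit(tab)
        assert not fit.weighted
        assert fit.slope == pytest.approx(1.0)


def test_analyze_batch_skips_short_episodes(rng):
    good = make_trace(5.0 * np.arange(1200) * T, conc=1.0)
    short = make_trace(5.0 * np.arange(300) * T, conc=1.0)
    tab = analyze_batch([good, short, good])
    assert len(tab) == 2


def test_trace_file_round_trip(tmp_path):
    tr = make_trace(np.linspace(0, 100, 1000), conc=1.5)
    f = tmp_path / "trace.tsv"
    tr.to_file(f)
    back = TipTrace.from_file(f, concentration=1.5)
    assert np.allclose(back.lengths, tr.lengths, atol=1e-3)
    assert back.t_exp == pytest.approx(T)
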