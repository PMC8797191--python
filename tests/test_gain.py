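"""Dynamic-gain estimator: ground-truth recovery on the Poisson fixture,
null calibration, denoising and cutoff machinery, scaling laws."""

import numpy as np
import pytest

from axodyn.gain import (DynamicGain, GainCurve, GainPipelineConfig,
                         compute_sta, cutoff_frequency, gaussian_denoise,
                         linear_response, loglog_slope)
from axodyn.stimulus import OUSpec, StimulusTrace, lowpass_transfer, \
    poisson_fixture

FIX_OU = OUSpec(mean=0.0, std=0.02, correlation_time=5.0, dt=0.5, seed=0)
FIX_TRANSFER = lowpass_transfer(gain0=50.0, corner_hz=30.0)


def fixture_config(n_trials, **kw):
    base = dict(n_trials=n_trials, dt=0.5, sta_dt=0.5, n_shift_surrogates=200)
    base.update(kw)
    return GainPipelineConfig(**base)


@pytest.fixture(scope="module")
def lowpass_data():
    return poisson_fixture(5.0, FIX_TRANSFER, FIX_OU, n_trials=200, seed=42)


@pytest.fixture(scope="module")
def lowpass_fit(lowpass_data):
    traces, trains = lowpass_data
    model = DynamicGain(traces, trains, FIX_OU, fixture_config(200))
    return model.fit(seed=1)


class TestSTA:
    def test_window_geometry_and_edge_decay(self, lowpass_data):
        traces, trains = lowpass_data
        sta = compute_sta(traces, trains, window=800.0, ou=FIX_OU,
                          config=fixture_config(200))
        assert sta.lags[0] == pytest.approx(-400.0)
        assert sta.lags[-1] == pytest.approx(400.0 - 0.5)
        core = np.abs(sta.sta_current[np.abs(sta.lags) < 20.0]).max()
        edge = np.abs(sta.sta_current[np.abs(sta.lags) > 300.0]).max()
        assert edge < 0.2 * core     # decayed into the noise floor

    def test_shuffled_pairing_kills_sta(self, lowpass_data):
        traces, trains = lowpass_data
        sta = compute_sta(traces, trains, ou=FIX_OU,
                          config=fixture_config(200))
        shuffled = trains[1:] + trains[:1]
        sta0 = compute_sta(traces, shuffled, ou=FIX_OU,
                           config=fixture_config(200))
        assert (np.abs(sta0.sta_current).max()
                < 0.2 * np.abs(sta.sta_current).max())

    def test_pointwise_variance_scales_inversely_with_trials(self,
                                                             lowpass_data):
        traces, trains = lowpass_data
        halves = []
        for sl in (slice(0, 100), slice(100, 200)):
            halves.append(compute_sta(traces[sl], trains[sl], ou=FIX_OU,
                                      config=fixture_config(100)).sta_current)
        full = compute_sta(traces, trains, ou=FIX_OU,
                           config=fixture_config(200)).sta_current
        # far from the spike the STA is noise; half the data, ~2x the variance
        far = np.abs(np.arange(-800, 800) * 0.5) > 200.0
        var_half = 0.5 * (halves[0][far].var() + halves[1][far].var())
        assert var_half / full[far].var() == pytest.approx(2.0, rel=0.6)

    def test_no_spikes_raises(self, lowpass_data):
        traces, trains = lowpass_data
        from axodyn.model import SpikeTrain

        empty = [SpikeTrain(spike_times=np.array([]),
                            trial_duration=t.trial_duration,
                            burn_in=t.burn_in) for t in trains[:3]]
        with pytest.raises(ValueError):
            compute_sta(traces[:3], empty, ou=FIX_OU,
                        config=fixture_config(3))


class TestLinearResponse:
    def test_psd_at_zero_frequency(self):
        ou = OUSpec(0.0, 0.5, 5.0, 0.1)
        assert ou.psd(0.0) == pytest.approx(2 * 5e-3 * 0.25)

    def test_analytic_vs_empirical_denominator(self, lowpass_data):
        """The two denominator modes agree over the mid-band (the stimulus
        is an exact OU, so its empirical spectrum matches the closed form)."""
        traces, trains = lowpass_data
        fits = {}
        for mode in ("analytic_psd", "empirical"):
            model = DynamicGain(traces, trains, FIX_OU,
                                fixture_config(200, denominator_mode=mode))
            sta = model.sta()
            centers, resp = model._response_from_sta(sta.sta_current,
                                                     sta.mean_rate)
            fits[mode] = (centers, np.abs(resp))
        band = (fits["analytic_psd"][0] >= 2.0) & \
               (fits["analytic_psd"][0] <= 200.0)
        ratio = fits["analytic_psd"][1][band] / fits["empirical"][1][band]
        assert np.all(np.abs(ratio - 1.0) < 0.10)

    def test_flat_filter_recovers_flat_gain(self):
        flat = lambda f: np.full_like(np.asarray(f, float), 40.0,
                                      dtype=complex)
        traces, trains = poisson_fixture(8.0, flat, FIX_OU, n_trials=120,
                                         seed=3)
        res = DynamicGain(traces, trains, FIX_OU,
                          fixture_config(120)).fit(seed=2,
                                                   compute_ci=True)
        c = res.curve
        # nearest-bin spike alignment at the fixture's 0.5 ms grid bounds
        # the usable band to ~200 Hz (sinc attenuation beyond)
        band = c.significant & (c.frequencies <= 200.0)
        inside = (40.0 >= c.ci_low[band]) & (40.0 <= c.ci_high[band])
        assert inside.mean() >= 0.9


class TestGaussianDenoise:
    def test_constant_preserved_and_delta_limit(self):
        f = np.fft.rfftfreq(1600, 5e-4)
        vals = np.full(f.size, 3.0 + 1.0j)
        _, out = gaussian_denoise(f, vals)
        assert np.allclose(out, 3.0 + 1.0j)
        rng = np.random.default_rng(0)
        noisy = rng.normal(size=f.size) + 1j * rng.normal(size=f.size)
        _, narrow = gaussian_denoise(f, noisy, fractional_width=1e-6)
        centers, _ = gaussian_denoise(f, noisy, fractional_width=1e-6)
        nearest = np.abs(f[None, :] - centers[:, None]).argmin(axis=1)
        assert np.allclose(narrow, noisy[nearest])

    def test_white_noise_variance_reduced(self):
        f = np.fft.rfftfreq(1600, 5e-4)
        rng = np.random.default_rng(1)
        noisy = rng.normal(size=(50, f.size)) + 1j * rng.normal(
            size=(50, f.size))
        centers, out = gaussian_denoise(f, noisy, fractional_width=0.25)
        hi = centers > 100.0    # wide filters at high frequency
        assert out[:, hi].var() < 0.25 * noisy.var()


class TestCutoff:
    def _curve(self, gain, freqs=None, sig=None):
        freqs = freqs if freqs is not None else np.logspace(0, 3, 61)
        n = freqs.size
        sig = sig if sig is not None else np.full(n, np.nan)
        return GainCurve(frequencies=freqs, response=gain.astype(complex),
                         gain=gain, ci_low=gain, ci_high=gain,
                         significance=sig)

    def test_single_pole_closed_form(self):
        f = np.logspace(0, 3, 121)
        f0 = 30.0
        curve = self._curve(100.0 / np.sqrt(1.0 + (f / f0) ** 2), freqs=f)
        assert cutoff_frequency(curve) == pytest.approx(np.sqrt(3) * f0,
                                                        rel=0.02)

    def test_flat_curve_undefined(self):
        curve = self._curve(np.full(61, 10.0))
        with pytest.raises(ValueError):
            cutoff_frequency(curve)
        assert cutoff_frequency(curve, strict=False) is None

    def test_entirely_insignificant_curve_raises(self):
        n = 61
        curve = self._curve(np.full(n, 1.0), sig=np.full(n, 5.0))
        with pytest.raises(ValueError):
            cutoff_frequency(curve)

    def test_slope_of_power_law(self):
        f = np.logspace(0, 3, 121)
        curve = self._curve(1000.0 * f ** -0.8, freqs=f)
        assert loglog_slope(curve, band=(30, 200)) == pytest.approx(-0.8,
                                                                    abs=1e-6)


class TestStatisticalMachinery:
    def test_null_false_positive_rate(self):
        traces, trains = poisson_fixture(5.0, None, FIX_OU, n_trials=80,
                                         seed=7)
        res = DynamicGain(traces, trains, FIX_OU,
                          fixture_config(80, n_shift_surrogates=300)).fit(
            seed=2, compute_ci=False)
        frac = (res.curve.gain > res.curve.significance).mean()
        assert frac <= 0.10

    def test_threshold_scales_with_spike_count(self, lowpass_data):
        """95% surrogate threshold drops ~1/sqrt(total spikes)."""
        traces, trains = lowpass_data
        thr = {}
        for n in (50, 200):
            model = DynamicGain(traces[:n], trains[:n], FIX_OU,
                                fixture_config(n))
            thr[n] = model.significance(seed=3, n_surrogates=150)
        ratio = np.median(thr[50] / thr[200])
        assert ratio == pytest.approx(2.0, rel=0.35)

    def test_ci_width_shrinks_with_trials(self, lowpass_data):
        traces, trains = lowpass_data
        widths = {}
        for n in (50, 200):
            model = DynamicGain(traces[:n], trains[:n], FIX_OU,
                                fixture_config(n))
            lo, hi = model.bootstrap(seed=4)
            widths[n] = np.median(hi - lo)
        assert widths[50] / widths[200] == pytest.approx(2.0, rel=0.4)

    def test_degenerate_bootstrap_is_tight(self):
        """Identical trials give (nearly) zero-width intervals."""
        ou = OUSpec(0.0, 0.02, 5.0, 0.5, seed=5)
        traces, trains = poisson_fixture(5.0, FIX_TRANSFER, ou, n_trials=1,
                                         seed=9)
        traces, trains = traces * 20, trains * 20
        model = DynamicGain(traces, trains, ou, fixture_config(20))
        lo, hi = model.bootstrap(seed=5)
        gain = np.abs(model._response_from_sta(model.sta().sta_current,
                                               model.sta().mean_rate)[1])
        assert np.allclose(lo, gain, rtol=1e-9)
        assert np.allclose(hi, gain, rtol=1e-9)

    def test_fixture_truth_within_ci(self, lowpass_fit):
        c = lowpass_fit.curve
        true = np.abs(FIX_TRANSFER(c.frequencies))
        sig = c.significant
        inside = (true >= c.ci_low) & (true <= c.ci_high)
        assert inside[sig].mean() >= 0.9

    def test_unit_linearity(self, lowpass_data):
        """Scaling the currents by c scales the gain by 1/c."""
        traces, trains = lowpass_data
        scale = 4.0
        scaled = [StimulusTrace(t.samples * scale, t.dt, t.kind,
                                t.generator_params) for t in traces[:60]]
        ou_scaled = OUSpec(0.0, FIX_OU.std * scale, 5.0, 0.5, seed=0)
        a = DynamicGain(traces[:60], trains[:60], FIX_OU,
                        fixture_config(60)).fit(seed=6, compute_ci=False,
                                                compute_significance=False)
        b = DynamicGain(scaled, trains[:60], ou_scaled,
                        fixture_config(60)).fit(seed=6, compute_ci=False,
                                                compute_significance=False)
        assert np.allclose(a.curve.gain, b.curve.gain * scale, rtol=1e-9)

    def test_same_seed_same_curve(self, lowpass_data):
        traces, trains = lowpass_data
        runs = [DynamicGain(traces[:40], trains[:40], FIX_OU,
                            fixture_config(40, n_shift_surrogates=50)).fit(
            seed=11) for _ in range(2)]
        assert np.array_equal(runs[0].curve.gain, runs[1].curve.gain)
        assert np.array_equal(runs[0].curve.significance,
                              runs[1].curve.significance)
        assert np.array_equal(runs[0].curve.ci_low, runs[1].curve.ci_low)

    def test_summary_mentions_key_quantities(self, lowpass_fit):
        text = lowpass_fit.summary()
        assert "cutoff" in text and "Hz/nA" in text
        assert str(lowpass_fit.model.n_trials) in text
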