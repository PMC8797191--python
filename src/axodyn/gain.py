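"""Dynamic-gain estimation from paired current traces and spike trains.

The population dynamic gain G(f) = |L(f)| is the magnitude of the linear
transfer function from injected-current modulation to instantaneous firing
rate.  For a stationary input it is estimated as

    L(f) = F[C_Inu] / F[C_II],

where the input-output correlation C_Inu(tau) equals the mean firing rate
times the zero-average spike-triggered average current (STA), windowed to
+-400 ms around the spike, and the denominator is the input power spectral
density (analytic for an OU stimulus, or the windowed empirical input
autocorrelation spectrum).  The complex Fourier components of the windowed
STA are de-noised with a bank of log-spaced Gaussian filters before taking
the magnitude.  Statistical machinery: a pointwise significance threshold
from cyclically time-shifted surrogate spike trains (null hypothesis: spikes
independent of the input), and bootstrap confidence intervals from resampled
trial-group STAs.

The estimator follows a statsmodels-like shape: ``DynamicGain`` is the model
bound to data, ``fit`` returns a ``DynamicGainResult`` carrying the gain
curve, its uncertainty and diagnostics, with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from ._kernels import sta_group_sums, surrogate_stas
from .model import DiscretizedCell, ResetPolicy, SpikeTrain, simulate_trial
from .stimulus import OUSpec, StimulusTrace, ou_generate, trial_seed

__all__ = [
    "GainPipelineConfig",
    "STAResult",
    "GainCurve",
    "DynamicGain",
    "DynamicGainResult",
    "compute_sta",
    "linear_response",
    "gaussian_denoise",
    "significance_threshold",
    "bootstrap_ci",
    "cutoff_frequency",
    "loglog_slope",
    "run_gain_pipeline",
]


@dataclass(frozen=True)
class GainPipelineConfig:
    """Estimation and simulation parameters of the gain pipeline.

    The reference study conditions are 20000 trials of 20 s (plus 0.5 s
    burn-in) at dt = 25 us; desk-scale runs reduce n_trials and coarsen the
    integration grid (subject to the spike-time convergence check).  The STA
    is accumulated at the integration step and decimated to sta_dt before
    the FFT; filter-bank geometry (log-spaced centers, fractional width) is
    reported in outputs because the gain at sharp spectral features depends
    on it.
    """

    n_trials: int = 20000
    trial_length: float = 20000.0      # ms of recorded time per trial
    burn_in: float = 500.0             # ms discarded at the trial start
    window: float = 800.0              # ms, STA window (centered)
    dt: float = 0.025                  # ms, integration step
    spatial_step: float = 1.0          # um, axon discretization
    soma_spatial_step: float | None = None
    sta_dt: float = 0.1                # ms, STA/FFT sampling after decimation
    f_max: float = 1000.0              # Hz, upper analysis frequency
    centers_per_decade: int = 20       # Gaussian filter bank geometry
    fractional_width: float = 0.25     # filter sigma = fractional_width * f_c
    n_shift_surrogates: int = 500
    shift_range: tuple | None = None   # ms; None -> (0.05, 0.95) * trial_length
    bootstrap_group_size: int = 50
    n_bootstrap_groups: int = 400
    n_bootstrap: int = 1000
    denominator_mode: str = "analytic_psd"   # or "empirical"

    def __post_init__(self):
        if self.denominator_mode not in ("analytic_psd", "empirical"):
            raise ValueError("denominator_mode must be analytic_psd or empirical")
        if self.n_trials < 1 or self.window <= 0 or self.sta_dt <= 0:
            raise ValueError("invalid pipeline configuration")
        lo, hi = self.effective_shift_range()
        if not 0 < lo < hi <= self.trial_length:
            raise ValueError("shift range must lie within the trial length")
        if self.bootstrap_group_size < 1 or self.n_bootstrap_groups < 1:
            raise ValueError("bootstrap grouping must be positive")
        # group_size * n_groups may exceed n_trials at desk scale; the
        # estimator then falls back to per-trial groups

    def effective_shift_range(self) -> tuple:
        if self.shift_range is not None:
            return self.shift_range
        return (0.05 * self.trial_length, 0.95 * self.trial_length)


def desk_config(**overrides) -> GainPipelineConfig:
    """Desk-scale defaults: a few hundred trials on a coarsened grid."""
    base = dict(n_trials=400, dt=0.05, spatial_step=4.0, soma_spatial_step=10.0)
    base.update(overrides)
    return GainPipelineConfig(**base)


@dataclass(frozen=True)
class STAResult:
    """Windowed zero-average spike-triggered average current.

    lags span [-window/2, window/2); C_Inu(tau) = mean_rate * sta_current.
    """

    lags: np.ndarray            # ms
    sta_current: np.ndarray     # nA, mean-subtracted
    n_spikes: int
    mean_rate: float            # Hz
    mean_current: float         # nA

    def __post_init__(self):
        if self.lags.shape != self.sta_current.shape:
            raise ValueError("lags and sta_current must have equal length")


@dataclass(frozen=True)
class GainCurve:
    """Dynamic gain on the filter-bank frequency grid with uncertainty.

    significance is the pointwise 95th-percentile surrogate curve (NaN when
    not computed); cutoff is the factor-2 decay frequency or None when the
    curve never falls that far inside the analysis band.
    """

    frequencies: np.ndarray     # Hz, strictly increasing
    response: np.ndarray        # complex L(f)
    gain: np.ndarray            # Hz/nA, |response|
    ci_low: np.ndarray
    ci_high: np.ndarray
    significance: np.ndarray
    cutoff: float | None = None

    def __post_init__(self):
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    @property
    def significant(self) -> np.ndarray:
        """Mask of frequencies where the gain exceeds the surrogate threshold."""
        with np.errstate(invalid="ignore"):
            mask = self.gain > self.significance
        return np.where(np.isnan(self.significance), True, mask)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "frequency_hz": self.frequencies,
            "gain": self.gain,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "significance": self.significance,
            "significant_flag": self.significant,
        })


# ---------------------------------------------------------------------------
# spectral helpers


def _fft_freqs(n_win: int, dt_sta_ms: float) -> np.ndarray:
    return np.fft.rfftfreq(n_win, dt_sta_ms * 1e-3)


def _windowed_spectrum(windowed: np.ndarray, half: int, dt_sta_ms: float):
    """Continuous-time Fourier transform of a lag-domain window.

    The array holds lags [-half, half) with lag 0 at index half; it is rolled
    so that lag 0 leads, making the FFT phase that of the centered transform.
    Returns the one-sided spectrum multiplied by the sample spacing (units:
    input units * s).
    """
    rolled = np.roll(windowed, -half, axis=-1)
    return np.fft.rfft(rolled, axis=-1) * (dt_sta_ms * 1e-3)


def gaussian_denoise(frequencies: np.ndarray, values: np.ndarray,
                     centers_per_decade: int = 20,
                     fractional_width: float = 0.25,
                     f_max: float = 1000.0,
                     centers: np.ndarray | None = None):
    """Gaussian filter bank on a uniform-grid complex spectrum.

    At each log-spaced output center f_c the complex components are averaged
    with Gaussian weights of standard deviation fractional_width * f_c; real
    and imaginary parts are smoothed jointly.  Constants are preserved and
    the output converges to the input as the width shrinks.  Returns
    (centers, denoised values).
    """
    frequencies = np.asarray(frequencies, dtype=float)
    values = np.asarray(values)
    if centers is None:
        centers = filter_bank_centers(frequencies, centers_per_decade, f_max)
    weights = _bank_weights(frequencies, centers, fractional_width)
    return centers, values @ weights.T


def filter_bank_centers(frequencies: np.ndarray, centers_per_decade: int,
                        f_max: float) -> np.ndarray:
    f0 = frequencies[frequencies > 0][0]
    n = int(np.floor(np.log10(f_max / f0) * centers_per_decade)) + 1
    centers = f0 * 10.0 ** (np.arange(n) / centers_per_decade)
    return centers[centers <= f_max * (1 + 1e-12)]


def _bank_weights(frequencies: np.ndarray, centers: np.ndarray,
                  fractional_width: float) -> np.ndarray:
    """(n_centers, n_freq) row-normalized Gaussian weights; the DC bin is
    excluded so the windowed-STA offset does not leak into the band."""
    f = frequencies[None, :]
    c = centers[:, None]
    sigma = np.maximum(fractional_width * c, 1e-12)
    w = np.exp(-0.5 * ((f - c) / sigma) ** 2)
    w[:, frequencies <= 0] = 0.0
    sums = w.sum(axis=1, keepdims=True)
    # underflowed rows (very narrow filters between grid points): nearest bin
    empty = sums[:, 0] <= 0
    if np.any(empty):
        pos = np.where(frequencies > 0, frequencies, np.inf)
        nearest = np.abs(pos[None, :] - c[empty]).argmin(axis=1)
        w[np.nonzero(empty)[0], nearest] = 1.0
        sums = w.sum(axis=1, keepdims=True)
    return w / sums


# ---------------------------------------------------------------------------
# the model object


class DynamicGain:
    """Dynamic-gain estimator bound to paired (current, spike-train) trials.

    Parameters
    ----------
    currents : sequence of StimulusTrace (or None when using from_trials)
    spike_trains : sequence of SpikeTrain, paired with the currents
    ou : OUSpec describing the stimulus ensemble (sigma and correlation_time
        set the analytic denominator)
    config : GainPipelineConfig; trial geometry must match the data

    ``fit`` runs the full estimation (STA, response, denoising, surrogate
    significance, bootstrap CI, cutoff) and returns a DynamicGainResult.
    """

    def __init__(self, currents: Sequence[StimulusTrace] | None,
                 spike_trains: Sequence[SpikeTrain],
                 ou: OUSpec, config: GainPipelineConfig | None = None):
        if config is None:
            config = GainPipelineConfig()
        self.config = config
        self.ou = ou
        self.trains = list(spike_trains)
        if currents is not None:
            if len(currents) != len(self.trains):
                raise ValueError("currents and spike_trains must be paired")
            self._ingest(iter(zip(currents, self.trains)))

    # -- construction ------------------------------------------------------

    @classmethod
    def from_trials(cls, trial_iter: Iterable, ou: OUSpec,
                    config: GainPipelineConfig | None = None) -> "DynamicGain":
        """Build from an iterable of (StimulusTrace, SpikeTrain) pairs,
        decimating each current on the fly (memory stays at the STA grid)."""
        obj = cls.__new__(cls)
        obj.config = config or GainPipelineConfig()
        obj.ou = ou
        obj.trains = []
        obj._ingest(trial_iter, collect_trains=True)
        return obj

    def _ingest(self, trial_iter, collect_trains: bool = False):
        cfg = self.config
        dec_rows, spike_t, trial_id, means = [], [], [], []
        factor = None
        for i, (trace, train) in enumerate(trial_iter):
            if collect_trains:
                self.trains.append(train)
            if factor is None:
                factor = max(1, int(round(cfg.sta_dt / trace.dt)))
                self._dt_sta = trace.dt * factor
                self._burn_in = train.burn_in
                self._duration = train.trial_duration
            s = trace.samples
            n_dec = s.size // factor
            dec = s[: n_dec * factor].reshape(n_dec, factor).mean(axis=1)
            means.append(dec.mean())
            dec_rows.append((dec - means[-1]).astype(np.float32))
            spike_t.append(train.spike_times)
            trial_id.append(np.full(train.n_spikes, i, dtype=np.int64))
        if factor is None:
            raise ValueError("no trials supplied")
        self._dec = np.vstack(dec_rows)
        self._spike_times = np.concatenate(spike_t) if spike_t else np.array([])
        self._trial_ids = np.concatenate(trial_id) if trial_id else \
            np.array([], dtype=np.int64)
        self._mean_current = float(np.mean(means))
        self._half = int(round(cfg.window / 2.0 / self._dt_sta))
        self._sta_cache = None
        self._group_cache = None
        self._den_cache = None

    # -- derived quantities ------------------------------------------------

    @property
    def n_trials(self) -> int:
        return self._dec.shape[0]

    @property
    def n_spikes(self) -> int:
        return int(self._spike_times.size)

    @property
    def mean_rate(self) -> float:
        total_ms = sum(t.trial_duration for t in self.trains)
        return self.n_spikes / total_ms * 1e3

    @property
    def lags(self) -> np.ndarray:
        return (np.arange(2 * self._half) - self._half) * self._dt_sta

    @property
    def frequencies(self) -> np.ndarray:
        return _fft_freqs(2 * self._half, self._dt_sta)

    def _groups(self):
        """Per-group STA sums (bootstrap resampling unit).  Falls back to
        per-trial groups when there are too few trials for the configured
        50-trial grouping."""
        if self._group_cache is None:
            cfg = self.config
            size = cfg.bootstrap_group_size
            if self.n_trials < size * cfg.n_bootstrap_groups:
                size = 1   # too few trials for the configured grouping
            n_groups = max(1, self.n_trials // size)
            group_of_trial = np.minimum(np.arange(self.n_trials) // size,
                                        n_groups - 1).astype(np.int64)
            sums, counts = sta_group_sums(
                self._dec, self._spike_times, self._trial_ids,
                group_of_trial, n_groups, self._dt_sta, self._half)
            self._group_cache = (sums, counts)
        return self._group_cache

    def sta(self) -> STAResult:
        """Grand windowed zero-average spike-triggered average."""
        if self._sta_cache is None:
            if self.n_spikes == 0:
                raise ValueError("no spikes: STA undefined")
            sums, counts = self._groups()
            total = counts.sum()
            if total == 0:
                raise ValueError("all spike windows clipped at trial edges")
            self._sta_cache = STAResult(
                lags=self.lags, sta_current=sums.sum(axis=0) / total,
                n_spikes=int(total), mean_rate=self.mean_rate,
                mean_current=self._mean_current)
        return self._sta_cache

    def _uniform_denominator(self) -> np.ndarray:
        if self._den_cache is None:
            if self.config.denominator_mode == "analytic_psd":
                den = self.ou.psd(self.frequencies)
            else:
                den = self._empirical_psd()
            den = np.where(den <= 0, np.inf, den)
            self._den_cache = den
        return self._den_cache

    def _empirical_psd(self, max_trials: int = 100) -> np.ndarray:
        """Windowed empirical input autocorrelation spectrum (C_II route)."""
        dec = self._dec[: max_trials].astype(np.float64)
        n = dec.shape[1]
        spec = np.abs(np.fft.rfft(dec, axis=1)) ** 2 / n
        acorr_full = np.fft.irfft(spec.mean(axis=0), n=n)
        windowed = np.empty(2 * self._half)
        windowed[self._half:] = acorr_full[: self._half]
        windowed[: self._half] = acorr_full[n - self._half:]
        return np.maximum(
            _windowed_spectrum(windowed, self._half, self._dt_sta).real, 1e-300)

    def _response_from_sta(self, sta_current: np.ndarray, rate_hz: float):
        """Complex L(f) on the filter-bank centers from one STA curve.

        The raw response (numerator over input PSD) is formed on the uniform
        FFT grid and the Gaussian bank then smooths the complex response
        itself: averaging the steeply falling numerator instead would bias
        the high-frequency tail upward through its convexity.
        """
        cfg = self.config
        c_inu = rate_hz * sta_current
        spectrum = _windowed_spectrum(c_inu, self._half, self._dt_sta)
        raw = spectrum / self._uniform_denominator()
        centers, resp = gaussian_denoise(
            self.frequencies, raw, cfg.centers_per_decade,
            cfg.fractional_width, cfg.f_max)
        return centers, resp

    # -- estimation --------------------------------------------------------

    def significance(self, seed: int = 0,
                     n_surrogates: int | None = None) -> np.ndarray:
        """Pointwise 95th-percentile gain under cyclic spike-time shifts.

        Every surrogate re-runs the full pipeline (STA -> response ->
        denoise -> magnitude) with all spikes of a trial shifted by one
        random interval; shifts never fall below 5% of the trial length, so
        no surrogate resembles the true alignment.
        """
        cfg = self.config
        n_surr = n_surrogates if n_surrogates is not None else cfg.n_shift_surrogates
        lo, hi = cfg.effective_shift_range()
        if hi > self._duration:
            lo, hi = 0.05 * self._duration, 0.95 * self._duration
        rng = np.random.default_rng(seed)
        shifts = rng.uniform(lo, hi, size=(n_surr, self.n_trials))
        stas, counts = surrogate_stas(
            self._dec, self._spike_times, self._trial_ids, shifts,
            self._burn_in, self._duration, self._dt_sta, self._half)
        counts = np.maximum(counts, 1)
        c_inu = self.mean_rate * stas / counts[:, None]
        spectra = _windowed_spectrum(c_inu, self._half, self._dt_sta)
        raw = spectra / self._uniform_denominator()[None, :]
        centers, resp = gaussian_denoise(
            self.frequencies, raw, cfg.centers_per_decade,
            cfg.fractional_width, cfg.f_max)
        return np.percentile(np.abs(resp), 95.0, axis=0)

    def bootstrap(self, seed: int = 0):
        """(ci_low, ci_high) of the gain from resampled trial-group STAs."""
        cfg = self.config
        sums, counts = self._groups()
        n_groups = sums.shape[0]
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n_groups, size=(cfg.n_bootstrap, n_groups))
        pick = np.zeros((cfg.n_bootstrap, n_groups))
        np.add.at(pick, (np.repeat(np.arange(cfg.n_bootstrap), n_groups),
                         idx.ravel()), 1.0)
        grand = (pick @ sums) / np.maximum(pick @ counts, 1.0)[:, None]
        c_inu = self.mean_rate * grand
        spectra = _windowed_spectrum(c_inu, self._half, self._dt_sta)
        raw = spectra / self._uniform_denominator()[None, :]
        centers, resp = gaussian_denoise(
            self.frequencies, raw, cfg.centers_per_decade,
            cfg.fractional_width, cfg.f_max)
        gains = np.abs(resp)
        return (np.percentile(gains, 2.5, axis=0),
                np.percentile(gains, 97.5, axis=0))

    def fit(self, seed: int = 0, compute_significance: bool = True,
            compute_ci: bool = True) -> "DynamicGainResult":
        sta = self.sta()
        centers, response = self._response_from_sta(sta.sta_current,
                                                    sta.mean_rate)
        gain = np.abs(response)
        if compute_significance:
            sig = self.significance(seed=seed + 1)
        else:
            sig = np.full_like(gain, np.nan)
        if compute_ci:
            ci_low, ci_high = self.bootstrap(seed=seed + 2)
        else:
            ci_low = ci_high = np.full_like(gain, np.nan)
        curve = GainCurve(frequencies=centers, response=response, gain=gain,
                          ci_low=ci_low, ci_high=ci_high, significance=sig)
        curve = replace(curve, cutoff=cutoff_frequency(curve, strict=False))
        return DynamicGainResult(model=self, curve=curve, sta=sta, seed=seed)


@dataclass
class DynamicGainResult:
    """Fitted dynamic gain: the curve, the underlying STA and diagnostics."""

    model: DynamicGain
    curve: GainCurve
    sta: STAResult
    seed: int

    @property
    def cutoff(self) -> float | None:
        return self.curve.cutoff

    def low_frequency_gain(self, f_upper: float = 2.0) -> float:
        """Mean gain over significant frequencies at or below f_upper Hz."""
        c = self.curve
        mask = (c.frequencies <= f_upper) & c.significant
        if not mask.any():
            raise ValueError("no significant frequencies below the bound")
        return float(c.gain[mask].mean())

    def high_frequency_slope(self, band=(30.0, 200.0)) -> float:
        return loglog_slope(self.curve, band=band)

    def summary(self) -> str:
        c = self.curve
        sig = c.significant
        band = (c.frequencies[sig].min(), c.frequencies[sig].max()) \
            if sig.any() else (np.nan, np.nan)
        lines = [
            "Dynamic gain estimate",
            "=====================",
            f"trials                {self.model.n_trials}",
            f"spikes (in STA)       {self.sta.n_spikes}",
            f"mean rate             {self.sta.mean_rate:8.3f} Hz",
            f"mean input current    {self.sta.mean_current:8.4f} nA",
            f"OU sigma / tau        {self.model.ou.std:.4f} nA / "
            f"{self.model.ou.correlation_time:.1f} ms",
            f"frequency band        {c.frequencies[0]:.2f} - "
            f"{c.frequencies[-1]:.1f} Hz ({c.frequencies.size} centers)",
            f"significant band      {band[0]:.2f} - {band[1]:.1f} Hz",
            f"low-frequency gain    {self._safe_lf():8.2f} Hz/nA",
            f"cutoff frequency      "
            + (f"{c.cutoff:8.2f} Hz" if c.cutoff is not None else "   undefined"),
            f"high-frequency slope  {self._safe_slope():8.3f} (log-log)",
        ]
        return "\n".join(lines)

    def _safe_lf(self):
        try:
            return self.low_frequency_gain()
        except ValueError:
            return float("nan")

    def _safe_slope(self):
        try:
            return self.high_frequency_slope()
        except ValueError:
            return float("nan")


# ---------------------------------------------------------------------------
# functional surface


def compute_sta(currents, spikes, window: float = 800.0,
                ou: OUSpec | None = None,
                config: GainPipelineConfig | None = None) -> STAResult:
    """Windowed zero-average STA of paired trials (see DynamicGain.sta)."""
    cfg = config or GainPipelineConfig(window=window)
    if cfg.window != window:
        cfg = replace(cfg, window=window)
    ou = ou or OUSpec(0.0, 1.0)
    return DynamicGain(currents, spikes, ou, cfg).sta()


def linear_response(sta: STAResult, ou: OUSpec,
                    mode: str = "analytic_psd",
                    currents=None) -> tuple:
    """Complex L(f) on the uniform FFT grid of the STA window (no denoising).

    Analytic mode divides by the OU power spectral density; empirical mode
    needs the currents to form the windowed input autocorrelation spectrum.
    """
    n_win = sta.lags.size
    half = n_win // 2
    dt_sta = float(sta.lags[1] - sta.lags[0])
    freqs = _fft_freqs(n_win, dt_sta)
    num = _windowed_spectrum(sta.mean_rate * sta.sta_current, half, dt_sta)
    if mode == "analytic_psd":
        den = ou.psd(freqs)
        den[freqs == 0] = ou.psd(0.0)
    elif mode == "empirical":
        if currents is None:
            raise ValueError("empirical mode requires the current traces")
        dg = DynamicGain(currents, _dummy_trains(currents), ou,
                         GainPipelineConfig(window=n_win * dt_sta,
                                            sta_dt=dt_sta))
        den = np.maximum(dg._empirical_psd(), 1e-300)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return freqs, num / den


def _dummy_trains(currents):
    return [SpikeTrain(spike_times=np.array([]),
                       trial_duration=c.duration, burn_in=0.0)
            for c in currents]


def significance_threshold(currents, spikes, ou: OUSpec,
                           config: GainPipelineConfig | None = None,
                           seed: int = 0):
    """(frequencies, threshold): 95th-percentile surrogate gain curve."""
    dg = DynamicGain(currents, spikes, ou, config)
    thr = dg.significance(seed=seed)
    centers = filter_bank_centers(dg.frequencies, dg.config.centers_per_decade,
                                  dg.config.f_max)
    return centers, thr


def bootstrap_ci(currents, spikes, ou: OUSpec,
                 config: GainPipelineConfig | None = None, seed: int = 0):
    """(frequencies, ci_low, ci_high) from trial-group bootstrap."""
    dg = DynamicGain(currents, spikes, ou, config)
    lo, hi = dg.bootstrap(seed=seed)
    centers = filter_bank_centers(dg.frequencies, dg.config.centers_per_decade,
                                  dg.config.f_max)
    return centers, lo, hi


def cutoff_frequency(curve: GainCurve, reference: str = "lowest_significant",
                     strict: bool = True) -> float | None:
    """Frequency at which the gain decays to half its reference value.

    reference 'lowest_significant' uses the gain at the lowest significant
    frequency (the curve's low-frequency plateau); 'peak' uses the maximum
    significant gain (relevant for resonant curves).  The crossing is found
    by log-linear interpolation and must persist for the following two grid
    points.  Returns None (strict=False) or raises (strict=True) when the
    gain never falls by a factor of two inside the band.
    """
    sig = curve.significant
    if not sig.any():
        if strict:
            raise ValueError(
                "gain curve entirely below the significance threshold")
        return None
    idx = np.nonzero(sig)[0]
    start = idx[0]
    if reference == "lowest_significant":
        ref = curve.gain[start]
    elif reference == "peak":
        ref = curve.gain[sig].max()
        start = int(np.argmax(np.where(sig, curve.gain, -np.inf)))
    else:
        raise ValueError(f"unknown reference {reference!r}")
    target = ref / 2.0
    g = curve.gain
    f = curve.frequencies
    n = g.size
    for i in range(start + 1, n):
        if g[i] <= target:
            later = g[i + 1: i + 3]
            if np.all(later <= target) or i >= n - 1:
                if g[i - 1] > target:
                    lf = np.log10(f[i - 1]) + (
                        (np.log10(g[i - 1]) - np.log10(target))
                        / (np.log10(g[i - 1]) - np.log10(g[i]))
                        * (np.log10(f[i]) - np.log10(f[i - 1])))
                    return float(10.0 ** lf)
                return float(f[i])
    if strict:
        raise ValueError("gain never decays to half its reference in-band")
    return None


def loglog_slope(curve: GainCurve, band=(30.0, 200.0),
                 significant_only: bool = True) -> float:
    """Straight-line slope of log10(gain) vs log10(f) over the band."""
    mask = (curve.frequencies >= band[0]) & (curve.frequencies <= band[1])
    if significant_only:
        mask &= curve.significant
    if mask.sum() < 3:
        raise ValueError("fewer than three usable frequencies in the band")
    x = np.log10(curve.frequencies[mask])
    y = np.log10(curve.gain[mask])
    return float(np.polyfit(x, y, 1)[0])


def run_gain_pipeline(cell: DiscretizedCell, policy: ResetPolicy,
                      mu: float, sigma: float, tau: float,
                      config: GainPipelineConfig | None = None,
                      seed: int = 0, compute_significance: bool = True,
                      compute_ci: bool = True) -> DynamicGainResult:
    """Simulate n_trials OU-driven trials and fit the dynamic gain.

    Per-trial stimuli use counter-based seeds derived from ``seed``, so the
    result is reproducible and trials are order-independent.  The cell is
    used as supplied; match config.dt/spatial_step to the cell when coarsened
    grids are intended.
    """
    cfg = config or GainPipelineConfig()
    n_steps = int(round((cfg.trial_length + cfg.burn_in) / cfg.dt))
    ou_ref = OUSpec(mu, sigma, tau, cfg.dt, seed=seed)

    def trials():
        for i in range(cfg.n_trials):
            spec = OUSpec(mu, sigma, tau, cfg.dt, seed=trial_seed(seed, i))
            trace = ou_generate(spec, n_steps)
            _, train = simulate_trial(cell, trace, policy, burn_in=cfg.burn_in)
            yield trace, train

    model = DynamicGain.from_trials(trials(), ou_ref, cfg)
    return model.fit(seed=seed, compute_significance=compute_significance,
                     compute_ci=compute_ci)
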