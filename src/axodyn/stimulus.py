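"""Synthetic input currents and an estimator-validation spike fixture.

The fluctuating background current is an Ornstein-Uhlenbeck process

    tau dI = (mu - I) dt + sqrt(2 tau) sigma dW

generated with the exact discretization (no Euler-Maruyama step bias): the
update I_{k+1} = mu + (I_k - mu) a + sigma sqrt(1 - a^2) xi with
a = exp(-dt/tau) preserves the stationary law N(mu, sigma^2) and the
exponential autocorrelation exp(-lag/tau) at any dt.  Its power spectral
density is P(f) = 2 tau sigma^2 / (1 + (2 pi tau f)^2).

``poisson_fixture`` draws inhomogeneous-Poisson spike trains whose rate is a
known linear functional of an OU current, so the dynamic-gain estimator can
be validated against an imposed ground-truth transfer function without the
neuron simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "OUSpec",
    "StimulusTrace",
    "ou_generate",
    "sinusoid",
    "constant",
    "slow_ramp",
    "trial_seed",
    "lowpass_transfer",
    "poisson_fixture",
]


@dataclass(frozen=True)
class OUSpec:
    """Ornstein-Uhlenbeck current parameters (nA, ms)."""

    mean: float
    std: float
    correlation_time: float = 5.0
    dt: float = 0.025
    seed: int = 0

    def __post_init__(self):
        if self.std < 0 or self.correlation_time <= 0 or self.dt <= 0:
            raise ValueError("require std >= 0, correlation_time > 0, dt > 0")

    def psd(self, f_hz):
        """Analytic power spectral density 2 tau sigma^2 / (1 + (2 pi tau f)^2).

        f_hz in Hz; returned in nA^2 * s (tau converted to seconds).
        """
        tau_s = self.correlation_time * 1e-3
        f = np.asarray(f_hz, dtype=float)
        return 2.0 * tau_s * self.std ** 2 / (1.0 + (2.0 * np.pi * tau_s * f) ** 2)


@dataclass(frozen=True)
class StimulusTrace:
    """A sampled current waveform (nA) with its generating parameters."""

    samples: np.ndarray
    dt: float
    kind: str
    generator_params: object = None

    def __post_init__(self):
        s = np.ascontiguousarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if s.size == 0:
            raise ValueError("empty stimulus")
        if not np.all(np.isfinite(s)):
            raise ValueError("non-finite stimulus samples")

    @property
    def n_steps(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_steps * self.dt

    def times(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt


def trial_seed(root_seed: int, trial_index: int) -> int:
    """Counter-based per-trial seed: reproducible regardless of execution order."""
    return int(np.random.SeedSequence([root_seed, trial_index]).generate_state(1)[0]
               % (2 ** 31))


def ou_generate(spec: OUSpec, n_steps: int) -> StimulusTrace:
    """Exact-discretization OU trace; the initial sample is stationary."""
    if n_steps <= 0:
        raise ValueError("n_steps must be > 0")
    rng = np.random.default_rng(spec.seed)
    a = np.exp(-spec.dt / spec.correlation_time)
    if spec.std == 0.0:
        return StimulusTrace(np.full(n_steps, spec.mean), spec.dt, "ou", spec)
    noise_scale = spec.std * np.sqrt(1.0 - a * a)
    xi = rng.standard_normal(n_steps)
    dev = np.empty(n_steps)
    dev[0] = spec.std * xi[0]
    # I_{k+1} - mu = a (I_k - mu) + noise_scale * xi : a scan, done in C below
    _ou_scan(dev, xi, a, noise_scale)
    return StimulusTrace(spec.mean + dev, spec.dt, "ou", spec)


def _ou_scan(dev, xi, a, noise_scale):
    # scipy.signal.lfilter implements the AR(1) recursion exactly
    from scipy.signal import lfilter

    drive = noise_scale * xi
    drive[0] = dev[0]
    dev[:] = lfilter([1.0], [1.0, -a], drive)


def sinusoid(amplitude: float, frequency: float, offset: float,
             dt: float, n_steps: int) -> StimulusTrace:
    """offset + amplitude*sin(2 pi f t); frequency in Hz, dt in ms."""
    nyquist = 1e3 / (2.0 * dt)
    if frequency >= nyquist:
        raise ValueError(f"frequency {frequency} Hz at or above Nyquist {nyquist} Hz")
    t_s = np.arange(n_steps) * dt * 1e-3
    params = {"amplitude": amplitude, "frequency": frequency, "offset": offset}
    return StimulusTrace(offset + amplitude * np.sin(2.0 * np.pi * frequency * t_s),
                         dt, "sinusoid", params)


def constant(level: float, dt: float, n_steps: int) -> StimulusTrace:
    return StimulusTrace(np.full(n_steps, float(level)), dt, "constant",
                         {"level": level})


def slow_ramp(start: float, end: float, duration: float, dt: float) -> StimulusTrace:
    """Linear current ramp start -> end over duration (ms)."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n = int(round(duration / dt))
    params = {"start": start, "end": end, "duration": duration}
    return StimulusTrace(np.linspace(start, end, n), dt, "ramp", params)


def lowpass_transfer(gain0: float, corner_hz: float) -> Callable[[np.ndarray], np.ndarray]:
    """First-order low-pass transfer function L(f) = gain0 / (1 + i f/f_c).

    gain0 in Hz/nA.  Returns a callable evaluating the complex response.
    """
    def transfer(f_hz):
        return gain0 / (1.0 + 1j * np.asarray(f_hz, dtype=float) / corner_hz)

    return transfer


def poisson_fixture(baseline_rate: float, transfer, ou: OUSpec, n_trials: int,
                    seed: int = 0, trial_length: float = 20000.0,
                    burn_in: float = 500.0):
    """Inhomogeneous-Poisson spike trains with an imposed linear response.

    The rate is nu(t) = nu0 + Re[ l * (I - mu) ](t) where l is the causal
    kernel whose Fourier transform is ``transfer`` (a callable of f in Hz; or
    None for input-independent homogeneous trains).  By construction the true
    dynamic gain equals |transfer(f)|.  Rates are clipped at zero; more than
    0.1% clipped samples raises (modulation too deep for a Poisson rate).

    Returns (traces, spike_trains) with the same conventions as the simulator.
    """
    from .model import SpikeTrain

    n_steps = int(round((trial_length + burn_in) / ou.dt))
    dt_s = ou.dt * 1e-3
    traces, trains = [], []
    # frequency response evaluated on the full-trace FFT grid (circular
    # convolution; the trace is long relative to the kernel support)
    f_grid = np.fft.rfftfreq(n_steps, dt_s)
    h = None if transfer is None else np.asarray(transfer(f_grid), dtype=complex)
    for i in range(n_trials):
        sp = OUSpec(ou.mean, ou.std, ou.correlation_time, ou.dt,
                    seed=trial_seed(seed, i))
        tr = ou_generate(sp, n_steps)
        if transfer is None:
            rate = np.full(n_steps, baseline_rate)
        else:
            mod = np.fft.irfft(np.fft.rfft(tr.samples - ou.mean) * h, n=n_steps)
            rate = baseline_rate + mod
        clipped = np.count_nonzero(rate < 0)
        if clipped > 1e-3 * n_steps:
            raise ValueError("modulation too deep: rate negative on "
                             f"{clipped / n_steps:.2%} of samples")
        rate = np.clip(rate, 0.0, None)
        rng = np.random.default_rng(trial_seed(seed + 2 ** 20, i))
        hits = rng.random(n_steps) < rate * dt_s
        times = (np.nonzero(hits)[0] + 0.5) * ou.dt
        times = times[times > burn_in]
        traces.append(tr)
        trains.append(SpikeTrain(spike_times=times, trial_duration=trial_length,
                                 burn_in=burn_in, seed=sp.seed))
    return traces, trains
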