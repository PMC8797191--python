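"""Operating-point calibration: find OU stimulus parameters (mu, sigma) that
hold a model variant at a prescribed firing rate and ISI irregularity.

Dynamic gain curves are only comparable between model variants probed at the
same operating point (rate nu, CV of the inter-spike-interval distribution),
so every experiment first calibrates the stimulus.  At fixed rate the CV is
controlled almost entirely by sigma and the rate by mu, which the nested
search exploits: an outer secant iteration on sigma targets the CV, an inner
bisection on mu re-targets the rate at each sigma.  All evaluations are pilot
simulations; the returned point is verified on fresh seeds.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, asdict

import numpy as np

from .model import DiscretizedCell, ResetPolicy, SpikeTrain, simulate_trial
from .stimulus import OUSpec, ou_generate, constant, trial_seed

__all__ = ["WorkingPoint", "OperatingPoint", "rate_cv", "find_operating_point",
           "fi_curve"]


@dataclass(frozen=True)
class WorkingPoint:
    """Target operating point.

    mode 'rate_and_cv' searches (mu, sigma) for both targets;
    'rate_and_fixed_std' holds sigma = fixed_std and searches mu for the rate.
    """

    target_rate: float = 5.0           # Hz
    rate_tolerance: float = 0.25       # Hz
    target_cv: float = 0.85
    cv_tolerance: float = 0.05
    mode: str = "rate_and_cv"
    fixed_std: float | None = None     # nA, for rate_and_fixed_std

    def __post_init__(self):
        if self.target_rate <= 0 or self.rate_tolerance <= 0 or self.cv_tolerance <= 0:
            raise ValueError("rate, rate_tolerance and cv_tolerance must be > 0")
        if self.mode not in ("rate_and_cv", "rate_and_fixed_std"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "rate_and_fixed_std" and self.fixed_std is None:
            raise ValueError("fixed_std required in rate_and_fixed_std mode")


@dataclass(frozen=True)
class OperatingPoint:
    """Calibrated stimulus parameters and the statistics they achieved."""

    mu: float                 # nA
    sigma: float              # nA
    rate: float               # Hz, on verification trials
    cv: float
    converged: bool
    n_iterations: int


def rate_cv(spike_trains) -> tuple[float, float]:
    """Pooled firing rate (Hz) and ISI coefficient of variation.

    Rate = total spikes / total recorded time; ISIs never span trial
    boundaries.  CV is NaN (signalled, not raised) with fewer than two ISIs.
    """
    trains = list(spike_trains)
    if not trains:
        raise ValueError("no spike trains")
    total_time_ms = sum(t.trial_duration for t in trains)
    n = sum(t.n_spikes for t in trains)
    rate = n / total_time_ms * 1e3
    isis = np.concatenate([np.diff(t.spike_times) for t in trains]) \
        if n else np.array([])
    if isis.size < 2:
        return rate, float("nan")
    return rate, float(np.std(isis) / np.mean(isis))


def _pilot_stats(cell, policy, mu, sigma, tau, seed, pilot_time, dt,
                 trial_length=20000.0, burn_in=500.0):
    """Simulate ceil(pilot_time/trial_length) trials; return (rate, cv)."""
    n_trials = max(1, int(math.ceil(pilot_time / trial_length)))
    n_steps = int(round((trial_length + burn_in) / dt))
    trains = []
    for i in range(n_trials):
        spec = OUSpec(mu, sigma, tau, dt, seed=trial_seed(seed, i))
        _, train = simulate_trial(cell, ou_generate(spec, n_steps), policy,
                                  burn_in=burn_in)
        trains.append(train)
    return rate_cv(trains)


def _solve_rate(cell, policy, sigma, tau, wp, seed, pilot_time, dt,
                mu_guess, max_iter=30):
    """Inner bisection on mu for the target rate at fixed sigma."""
    rate = lambda mu, s: _pilot_stats(cell, policy, mu, sigma, tau, s,
                                      pilot_time, dt)
    lo, hi = 0.0, max(mu_guess, 1e-3)
    r_hi, cv_hi = rate(hi, seed)
    k = 0
    while r_hi < wp.target_rate and k < 12:
        lo, hi = hi, hi * 1.6 + 0.01
        r_hi, cv_hi = rate(hi, seed + 1000 + k)
        k += 1
    mu, r, cv = hi, r_hi, cv_hi
    for j in range(max_iter):
        if abs(r - wp.target_rate) <= wp.rate_tolerance * 0.8:
            break
        if r < wp.target_rate:
            lo = mu
        else:
            hi = mu
        mu = 0.5 * (lo + hi)
        r, cv = rate(mu, seed + 2000 + j)
    return mu, r, cv


def find_operating_point(cell: DiscretizedCell, policy: ResetPolicy,
                         wp: WorkingPoint, tau: float, seed: int = 0,
                         dt: float = 0.05, pilot_time: float = 200000.0,
                         max_outer: int = 25, mu_guess: float | None = None,
                         sigma_guess: float | None = None,
                         cache_dir: str | None = None) -> OperatingPoint:
    """Search (mu, sigma) putting the model at the working point.

    tau: OU correlation time (ms); pilot_time: simulated time (ms) per
    evaluation; verification runs on fresh seeds so the tolerances are met
    out-of-sample.  Non-convergence returns the best point found with
    converged=False rather than raising.
    """
    if cache_dir is not None:
        key = _cache_key(cell, policy, wp, tau, dt)
        cached = _cache_load(cache_dir, key)
        if cached is not None:
            return cached

    if mu_guess is None:
        # scale with total membrane area relative to the default geometry
        area = float(np.sum(cell.node_leak_conductance))
        mu_guess = 0.08 * area / 3.25e-3
    if sigma_guess is None:
        # at fixed rate and CV, the required noise amplitude falls with the
        # correlation time (slow fluctuations spread ISIs more effectively)
        sigma_guess = 0.6 * mu_guess * (5.0 / tau) ** 0.7
    sigma = wp.fixed_std if wp.mode == "rate_and_fixed_std" else sigma_guess

    history = []  # (sigma, cv) pairs for the secant update
    mu, r, cv = mu_guess, None, None
    best = None
    n_iter = 0
    for outer in range(max_outer):
        n_iter = outer + 1
        mu, r, cv = _solve_rate(cell, policy, sigma, tau, wp,
                                seed + 10000 * outer, pilot_time, dt, mu)
        cand = (abs(cv - wp.target_cv) if wp.mode == "rate_and_cv" else 0.0,
                mu, sigma, r, cv)
        if best is None or cand[0] < best[0]:
            best = cand
        if wp.mode == "rate_and_fixed_std":
            break
        if abs(cv - wp.target_cv) <= wp.cv_tolerance * 0.8:
            break
        history.append((sigma, cv))
        if len(history) >= 2 and history[-1][1] != history[-2][1]:
            (s0, c0), (s1, c1) = history[-2], history[-1]
            sigma_new = s1 + (wp.target_cv - c1) * (s1 - s0) / (c1 - c0)
        else:
            sigma_new = sigma * (1.35 if cv < wp.target_cv else 0.7)
        sigma = float(np.clip(sigma_new, 0.25 * sigma, 4.0 * sigma))

    _, mu, sigma, r, cv = best
    # verification on held-out seeds
    v_rate, v_cv = _pilot_stats(cell, policy, mu, sigma, tau,
                                seed + 777_000, pilot_time, dt)
    ok = abs(v_rate - wp.target_rate) <= wp.rate_tolerance and (
        wp.mode == "rate_and_fixed_std"
        or abs(v_cv - wp.target_cv) <= wp.cv_tolerance)
    result = OperatingPoint(mu=float(mu), sigma=float(sigma), rate=v_rate,
                            cv=v_cv, converged=bool(ok), n_iterations=n_iter)
    if cache_dir is not None and ok:
        _cache_store(cache_dir, key, result)
    return result


def fi_curve(cell: DiscretizedCell, policy: ResetPolicy, currents,
             duration: float = 4000.0, discard: float = 1000.0,
             dt: float = 0.05) -> np.ndarray:
    """Firing rate (Hz) versus constant injected current (the F-I curve)."""
    rates = []
    for i_const in currents:
        stim = constant(float(i_const), dt, int(round(duration / dt)))
        _, train = simulate_trial(cell, stim, policy, burn_in=discard)
        rates.append(train.rate)
    return np.asarray(rates)


def _cache_key(cell, policy, wp, tau, dt) -> str:
    payload = {
        "morph": asdict(cell.morphology), "passive": asdict(cell.passive),
        "sodium": asdict(cell.sodium), "policy": asdict(policy),
        "wp": asdict(wp), "tau": tau, "dt": dt,
    }
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _cache_load(cache_dir, key):
    path = os.path.join(cache_dir, f"op_{key}.json")
    if os.path.exists(path):
        with open(path) as fh:
            return OperatingPoint(**json.load(fh))
    return None


def _cache_store(cache_dir, key, op: OperatingPoint):
    os.makedirs(cache_dir, exist_ok=True)
    with open(os.path.join(cache_dir, f"op_{key}.json"), "w") as fh:
        json.dump(asdict(op), fh, indent=1)
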