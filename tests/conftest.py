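"""Shared fixtures: calibrated policies, operating points and gain runs.

The expensive objects (threshold calibration, operating-point search, the
300-trial baseline gain estimate) are session-scoped so the acceptance and
property tests share one computation.  All randomness is seeded.
"""

import numpy as np
import pytest

from axodyn.calibration import WorkingPoint, find_operating_point
from axodyn.gain import desk_config, run_gain_pipeline
from axodyn.model import (MorphologySpec, PassiveSpec, SodiumSpec, build_cell,
                          calibrate_thresholds)

# desk-scale discretization used by simulation-heavy tests (convergence of
# this coarsening against the reference grid is itself under test)
COARSE = dict(spatial_step=4.0, soma_spatial_step=10.0)
DT = 0.05


def coarse_cell(x_na=40.0, soma=50.0, k_a=6.0, gbar_mult=1.0, r_a=150.0,
                region_overrides=()):
    morph = MorphologySpec(soma_diameter=soma, soma_length=soma,
                           na_position=x_na, **COARSE)
    passive = PassiveSpec(axial_resistivity=r_a,
                          region_overrides=region_overrides)
    sodium = SodiumSpec(peak_conductance=5.23e-9 * gbar_mult, slope=k_a)
    return build_cell(morph, passive, sodium)


@pytest.fixture(scope="session")
def baseline_cell():
    return coarse_cell()


@pytest.fixture(scope="session")
def fine_cell():
    return build_cell()


@pytest.fixture(scope="session")
def baseline_policy(baseline_cell):
    return calibrate_thresholds(baseline_cell, 5.0, dt=DT)


@pytest.fixture(scope="session")
def baseline_op(baseline_cell, baseline_policy):
    """(mu, sigma) at the 5 Hz / CV 0.85 operating point, tau = 5 ms."""
    return find_operating_point(baseline_cell, baseline_policy,
                                WorkingPoint(), tau=5.0, seed=11,
                                pilot_time=300000.0, dt=DT)


@pytest.fixture(scope="session")
def baseline_gain(baseline_cell, baseline_policy, baseline_op):
    """The scaled-down reference pipeline: 300 trials with significance and
    bootstrap machinery at the calibrated operating point."""
    cfg = desk_config(n_trials=300, n_shift_surrogates=500)
    return run_gain_pipeline(baseline_cell, baseline_policy,
                             baseline_op.mu, baseline_op.sigma, 5.0,
                             cfg, seed=5)


def quick_gain(cell, tau, seed, n_trials=80, policy=None,
               sigma_guess=None, reset_voltage=None):
    """Loose-tolerance calibrated gain run for trend comparisons.

    Uses the per-experiment tolerance override (rate +-0.5 Hz, CV +-0.1)
    with short pilots; trend assertions compare large qualitative effects.
    """
    if policy is None:
        policy = calibrate_thresholds(cell, 5.0, dt=DT,
                                      reset_voltage=reset_voltage)
    wp = WorkingPoint(rate_tolerance=0.5, cv_tolerance=0.1)
    op = find_operating_point(cell, policy, wp, tau=tau, seed=seed,
                              pilot_time=80000.0, dt=DT, max_outer=8,
                              sigma_guess=sigma_guess)
    cfg = desk_config(n_trials=n_trials)
    res = run_gain_pipeline(cell, policy, op.mu, op.sigma, tau, cfg,
                            seed=seed + 1, compute_significance=False,
                            compute_ci=False)
    return op, res


def band_average(curve, lo, hi):
    mask = (curve.frequencies >= lo) & (curve.frequencies <= hi)
    return float(curve.gain[mask].mean())


def matched_spike_fraction(a, b, tol):
    """Fraction of spikes in `a` with a partner in `b` within tol ms.

    Occasional near-threshold spikes appear or vanish under grid refinement;
    greedy nearest matching keeps one marginal event from misaligning the
    whole comparison."""
    a, b = np.asarray(a), np.asarray(b)
    if a.size == 0:
        return 1.0
    used = np.zeros(b.size, dtype=bool)
    hit = 0
    for t in a:
        i = int(np.argmin(np.abs(b - t))) if b.size else -1
        if i >= 0 and not used[i] and abs(b[i] - t) < tol:
            used[i] = True
            hit += 1
    return hit / a.size
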