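"""Passive transfer impedance (soma to axon) and AP phase-plane extraction.

The transfer impedance quantifies how the cable filters a somatic current
before it reaches the AP initiation site: |Z(f)| is the axonal voltage
amplitude per unit injected current amplitude.  Two routes are provided:
sinusoidal probing of the passive cell (sodium removed) and the
cross-spectral estimate under OU stimulation, which also applies to the
intact model in its subthreshold regime.  Phase plots (dV/dt vs V) of the
AP upstroke characterize initiation rapidness; curves are compared after
translating the pre-upstroke local minimum of dV/dt to the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .model import DiscretizedCell, SodiumSpec, simulate_trial, passive_steady_state
from .stimulus import OUSpec, StimulusTrace, ou_generate, sinusoid

__all__ = [
    "ImpedanceCurve",
    "PhasePlot",
    "passive_cell",
    "transfer_impedance_sine",
    "transfer_impedance_ou",
    "dc_transfer_resistance",
    "phase_plot",
    "extract_ap_upstroke",
]


@dataclass(frozen=True)
class ImpedanceCurve:
    """Transfer impedance magnitude (MOhm) from somatic injection to a probe."""

    frequencies: np.ndarray     # Hz
    magnitude: np.ndarray       # MOhm (mV per nA)
    probe_position: float       # um from the soma-axon junction

    def __post_init__(self):
        if np.any(self.magnitude <= 0):
            raise ValueError("impedance magnitude must be positive")


@dataclass(frozen=True)
class PhasePlot:
    """dV/dt versus V of one voltage trace, optionally origin-aligned."""

    voltage: np.ndarray           # mV
    dvdt: np.ndarray              # mV/ms
    alignment_offset: tuple       # (mV, mV/ms) subtracted from the raw curve


def passive_cell(cell: DiscretizedCell) -> DiscretizedCell:
    """The same cell with the sodium peak conductance set to zero."""
    return cell.with_specs(sodium=replace(cell.sodium, peak_conductance=0.0))


def _probe_node(cell: DiscretizedCell, probe_um: float | None) -> int:
    if probe_um is None:
        return cell.na_node
    return cell.n_soma + int(np.argmin(np.abs(cell.axon_positions - probe_um)))


def dc_transfer_resistance(cell: DiscretizedCell, probe_um: float | None = None) -> float:
    """Algebraic DC limit: stationary axonal voltage change per nA injected."""
    pc = passive_cell(cell)
    node = _probe_node(pc, probe_um)
    v0 = passive_steady_state(pc, 0.0)[node]
    v1 = passive_steady_state(pc, 1.0)[node]
    return float(v1 - v0)


def transfer_impedance_sine(cell: DiscretizedCell, frequencies,
                            probe_um: float | None = None,
                            amplitude: float = 0.01, dt: float = 0.025,
                            n_cycles: int = 10, n_transient: int = 5,
                            max_duration: float = 20000.0) -> ImpedanceCurve:
    """Sinusoidal transfer impedance of the passive cell.

    Per frequency: inject offset-free sine at the soma, discard n_transient
    cycles (at least half a second for the slowest), and take the amplitude
    ratio at the stimulus frequency bin of the recorded axonal voltage.
    """
    pc = passive_cell(cell)
    node = _probe_node(pc, probe_um)
    mags = []
    for f in np.asarray(frequencies, dtype=float):
        period = 1e3 / f
        t_trans = max(n_transient * period, 500.0)
        t_meas = n_cycles * period
        if t_trans + t_meas > max_duration:
            t_meas = max(period, max_duration - t_trans)
        n_steps = int(round((t_trans + t_meas) / dt))
        stim = sinusoid(amplitude, f, 0.0, dt, n_steps)
        traces, _ = simulate_trial(pc, stim, None, record_nodes=[node],
                                   burn_in=min(t_trans, stim.duration - dt))
        v = traces[node][int(round(t_trans / dt)):]
        n = v.size - (v.size % max(1, int(round(period / dt))))
        v = v[:n]
        k = int(round(f * n * dt * 1e-3))   # cycles in the measured segment
        comp = np.fft.rfft(v - v.mean())[k]
        mags.append(2.0 * np.abs(comp) / n / amplitude)
    return ImpedanceCurve(frequencies=np.asarray(frequencies, dtype=float),
                          magnitude=np.asarray(mags), probe_position=float(
                              cell.axon_positions[_probe_node(cell, probe_um)
                                                  - cell.n_soma]))


def transfer_impedance_ou(cell: DiscretizedCell, ou: OUSpec,
                          probe_um: float | None = None,
                          duration: float = 100000.0,
                          nperseg_ms: float = 4000.0,
                          policy=None) -> ImpedanceCurve:
    """Cross-spectral transfer impedance under OU stimulation.

    |Z(f)| = |S_IV(f)| / S_II(f), Welch-averaged.  Works on the passive cell
    or on the intact model in a subthreshold operating regime (pass the
    policy to keep forced resets, or None for free dynamics).
    """
    node = _probe_node(cell, probe_um)
    n_steps = int(round(duration / ou.dt))
    stim = ou_generate(ou, n_steps)
    traces, _ = simulate_trial(cell, stim, policy, record_nodes=[node],
                               burn_in=500.0)
    k0 = int(round(500.0 / ou.dt))
    v = traces[node][k0:]
    x = stim.samples[k0: k0 + v.size]
    fs = 1e3 / ou.dt
    nper = int(round(nperseg_ms / ou.dt))
    f, s_iv = sps.csd(x, v, fs=fs, nperseg=nper)
    _, s_ii = sps.welch(x, fs=fs, nperseg=nper)
    keep = (f > 0) & (f <= 1000.0)
    return ImpedanceCurve(frequencies=f[keep],
                          magnitude=np.abs(s_iv[keep]) / s_ii[keep],
                          probe_position=float(
                              cell.axon_positions[node - cell.n_soma]))


def extract_ap_upstroke(voltage: np.ndarray, dt: float,
                        pre_ms: float = 5.0, post_ms: float = 0.0):
    """Segment of the trace around the fastest upstroke (one AP)."""
    dvdt = np.gradient(voltage, dt)
    k = int(np.argmax(dvdt))
    lo = max(0, k - int(round(pre_ms / dt)))
    hi = min(voltage.size, k + max(1, int(round(post_ms / dt))) + 1)
    return voltage[lo:hi]


def phase_plot(voltage: np.ndarray, dt: float,
               alignment: str = "none") -> PhasePlot:
    """(V, dV/dt) trajectory by central differences at the recording step.

    alignment='local_minimum' translates the last local minimum of dV/dt
    preceding the fastest upstroke (the pre-upstroke trough between resting
    drift and AP initiation) to (0 mV, 0 mV/ms).
    """
    voltage = np.asarray(voltage, dtype=float)
    dvdt = np.gradient(voltage, dt)
    if alignment == "none":
        return PhasePlot(voltage=voltage, dvdt=dvdt, alignment_offset=(0.0, 0.0))
    if alignment != "local_minimum":
        raise ValueError(f"unknown alignment {alignment!r}")
    k_up = int(np.argmax(dvdt))
    seg = dvdt[:k_up]
    if seg.size < 3:
        raise ValueError("no pre-upstroke segment to align on")
    minima = np.nonzero((seg[1:-1] <= seg[:-2]) & (seg[1:-1] <= seg[2:]))[0] + 1
    if minima.size == 0:
        k_min = int(np.argmin(seg))
        if k_min in (0, seg.size - 1):
            raise ValueError("no identifiable local minimum of dV/dt")
    else:
        k_min = int(minima[-1])
    off = (voltage[k_min], dvdt[k_min])
    return PhasePlot(voltage=voltage - off[0], dvdt=dvdt - off[1],
                     alignment_offset=off)
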