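"""Steady-state analysis of axo-somatic voltage decoupling.

With the somatic voltage clamped, the only nonlinearity — the sodium point
conductance — sees the rest of the cell as a linear (Thevenin) one-port:
the net non-sodium current leaving the sodium node is an affine function of
the node voltage, I_lat(V_A) = g_eff * (V_A - V_open).  Stationary axonal
voltages are the roots of

    gbar_Na * m_inf(V_A) * (E_Na - V_A) = I_lat(V_A),

and the generic root count is one or three.  As the sodium site moves away
from the soma the effective conductance falls; beyond a critical distance a
fold bifurcation appears and an upward quasi-static clamp sweep shows a
discontinuous jump of the stationary axonal voltage.  The lateral-current
convention here includes the sodium node's own leak (the reduction is of the
complete passive network), which makes the intersection condition exactly
the stationarity condition of the full model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded
from scipy.optimize import brentq

from ._kernels import relax_clamped_kernel
from .model import DiscretizedCell, ResetPolicy, m_inf, _banded_matrix
from .stimulus import StimulusTrace

__all__ = [
    "EquilibriumSet",
    "BifurcationScan",
    "lateral_current_line",
    "axonal_equilibria",
    "critical_distance",
    "fold_voltage",
    "vclamp_sweep",
    "cclamp_ramp",
    "bifurcation_scan",
]


@dataclass(frozen=True)
class EquilibriumSet:
    """Stationary axonal voltages for one clamped somatic voltage.

    equilibria: list of (voltage mV, stable flag); lateral_line holds the
    Thevenin reduction (effective conductance uS, offset current nA) with
    I_lat(V_A) = conductance * V_A + offset.
    """

    clamped_somatic_voltage: float
    equilibria: tuple
    lateral_line: tuple

    @property
    def voltages(self) -> np.ndarray:
        return np.array([v for v, _ in self.equilibria])

    @property
    def n_equilibria(self) -> int:
        return len(self.equilibria)

    @property
    def stable_voltages(self) -> np.ndarray:
        return np.array([v for v, s in self.equilibria if s])


@dataclass(frozen=True)
class BifurcationScan:
    """Equilibrium branches over (x_Na, clamped somatic voltage) grids."""

    x_na_grid: np.ndarray
    v_soma_grid: np.ndarray
    branches: list               # list of (x_na, v_soma, v_axon, stable) tuples
    critical_distance: float
    jump_voltages: dict          # x_na -> somatic fold voltage (x beyond critical)


def _clamped_passive_solve(cell: DiscretizedCell, clamp_v: float,
                           i_na: float) -> np.ndarray:
    """Passive profile with the injection node clamped and i_na injected at
    the sodium node (Dirichlet row in the banded conductance matrix)."""
    ab = _banded_matrix(cell)
    b = cell.node_leak_conductance * cell.passive.leak_reversal
    c = cell.injection_node
    # Dirichlet row: V[c] = clamp_v
    ab[1, c] = 1.0
    if c + 1 < cell.n_nodes:
        ab[0, c + 1] = 0.0   # superdiagonal entry of row c
    if c - 1 >= 0:
        ab[2, c - 1] = 0.0   # subdiagonal entry of row c
    b[c] = clamp_v
    b[cell.na_node] += i_na
    return solve_banded((1, 1), ab, b)


def lateral_current_line(cell: DiscretizedCell, v_soma_clamp: float):
    """Thevenin reduction of the clamped passive cell seen from the sodium node.

    Returns (conductance uS, offset nA) such that the net non-sodium current
    leaving the sodium node is I_lat(V_A) = conductance * V_A + offset; the
    offset satisfies I_lat(V_open) = 0 at the clamped passive profile voltage.
    Exact, via two linear solves (zero and unit current at the sodium node).
    """
    v0 = _clamped_passive_solve(cell, v_soma_clamp, 0.0)[cell.na_node]
    v1 = _clamped_passive_solve(cell, v_soma_clamp, 1.0)[cell.na_node]
    g_eff = 1.0 / (v1 - v0)
    return g_eff, -g_eff * v0


def _net_current(cell: DiscretizedCell, v_a, g_eff, offset):
    """Sodium current minus lateral current at axonal voltage v_a (nA)."""
    sod = cell.sodium
    i_na = cell.gbar_us * m_inf(v_a, sod) * (sod.reversal - v_a)
    return i_na - (g_eff * v_a + offset)


def axonal_equilibria(cell: DiscretizedCell, v_soma_clamp: float,
                      v_bounds=(-80.0, 60.0), scan_step: float = 0.02) -> EquilibriumSet:
    """Stationary axonal voltages under somatic clamp with stability flags.

    Roots of the sodium-vs-lateral current balance are bracketed by a
    sign-change scan and polished with Brent's method; a root is stable when
    the net current has negative slope there (the rest of the system is
    linear and stable, so the scalar reduction decides stability).
    """
    g_eff, offset = lateral_current_line(cell, v_soma_clamp)
    grid = np.arange(v_bounds[0], v_bounds[1] + scan_step, scan_step)
    fv = _net_current(cell, grid, g_eff, offset)
    roots = []
    sign_change = np.nonzero(np.sign(fv[:-1]) * np.sign(fv[1:]) < 0)[0]
    for i in sign_change:
        r = brentq(lambda v: _net_current(cell, v, g_eff, offset),
                   grid[i], grid[i + 1], xtol=1e-12)
        eps = 1e-6
        slope = (_net_current(cell, r + eps, g_eff, offset)
                 - _net_current(cell, r - eps, g_eff, offset)) / (2 * eps)
        roots.append((float(r), bool(slope < 0)))
    for i in np.nonzero(fv == 0.0)[0]:  # exact grid hits
        roots.append((float(grid[i]), True))
    roots.sort()
    return EquilibriumSet(clamped_somatic_voltage=v_soma_clamp,
                          equilibria=tuple(roots),
                          lateral_line=(float(g_eff), float(offset)))


def _sodium_iv(cell: DiscretizedCell, v):
    sod = cell.sodium
    return cell.gbar_us * m_inf(v, sod) * (sod.reversal - v)


def _sodium_iv_slope(cell: DiscretizedCell, v):
    sod = cell.sodium
    m = m_inf(v, sod)
    mp = m * (1.0 - m) / sod.slope
    return cell.gbar_us * (mp * (sod.reversal - v) - m)


def _fold_window(cell: DiscretizedCell):
    """Offset-current window for which the equilibrium balance has three roots.

    phi(V) = I_Na(V) - g_eff V has a local minimum at V1 and a local maximum
    at V2 (the two voltages where the sodium I-V slope equals g_eff); the
    root condition phi(V) = offset has three solutions exactly for offsets in
    (phi(V1), phi(V2)).  Returns (g_eff, off_low, off_high) or None when the
    sodium curve is never steeper than the lateral line (no fold possible).
    Exact up to root polishing; no gridding over clamp voltages.
    """
    g_eff, _ = lateral_current_line(cell, -60.0)
    grid = np.linspace(-80.0, 59.0, 2000)
    psi = _sodium_iv_slope(cell, grid) - g_eff
    idx = np.nonzero(np.sign(psi[:-1]) * np.sign(psi[1:]) < 0)[0]
    if idx.size < 2:
        return None
    crit = [brentq(lambda v: _sodium_iv_slope(cell, v) - g_eff,
                   grid[i], grid[i + 1], xtol=1e-10) for i in idx[:2]]
    v1, v2 = sorted(crit)
    phi = lambda v: _sodium_iv(cell, v) - g_eff * v
    return g_eff, phi(v1), phi(v2)


def _offset_affine(cell: DiscretizedCell, v_lo: float, v_hi: float):
    """offset(V_c) of the lateral line is affine in the clamp voltage."""
    g_eff, off_lo = lateral_current_line(cell, v_lo)
    _, off_hi = lateral_current_line(cell, v_hi)
    slope = (off_hi - off_lo) / (v_hi - v_lo)
    return g_eff, off_lo, slope


def _is_multistable(cell: DiscretizedCell, x_na: float, v_soma_range) -> bool:
    """Three equilibria for some clamped somatic voltage within the range."""
    cx = cell.with_sodium_position(x_na)
    window = _fold_window(cx)
    if window is None:
        return False
    _, off_min, off_max = window
    v_lo, v_hi = float(v_soma_range[0]), float(v_soma_range[-1])
    _, off_at_lo, slope = _offset_affine(cx, v_lo, v_hi)
    offs = sorted((off_at_lo, off_at_lo + slope * (v_hi - v_lo)))
    return offs[0] < off_max and offs[1] > off_min


def critical_distance(cell: DiscretizedCell, v_soma_range=(-60.0, -50.0),
                      x_bounds=(5.0, 40.0), x_tol: float = 0.1) -> float:
    """Smallest sodium-site distance with three coexisting axonal equilibria
    for some clamped somatic voltage in v_soma_range; bisected on x_Na to
    x_tol (bounded below by the axon grid resolution, since the sodium site
    snaps to the nearest node)."""
    x_lo, x_hi = x_bounds
    if _is_multistable(cell, x_lo, v_soma_range):
        raise ValueError("multistable already at the lower x bound")
    if not _is_multistable(cell, x_hi, v_soma_range):
        raise ValueError("no multistability anywhere in the scanned range")
    while x_hi - x_lo > x_tol:
        mid = 0.5 * (x_lo + x_hi)
        if _is_multistable(cell, mid, v_soma_range):
            x_hi = mid
        else:
            x_lo = mid
    return 0.5 * (x_lo + x_hi)


def fold_voltage(cell: DiscretizedCell, v_soma_range=(-60.0, -50.0)) -> float:
    """Clamped somatic voltage at which the lower stable axonal branch
    vanishes during an upward sweep (the fold of the equilibrium set).

    The lower branch exists while the lateral-line offset exceeds the local
    minimum of phi(V) = I_Na - g_eff V; the offset is affine and decreasing
    in the clamp voltage, so the fold solves offset(V_c) = phi(V1) exactly.
    """
    window = _fold_window(cell)
    if window is None:
        raise ValueError("no fold: sodium curve never steeper than lateral line")
    _, off_min, _ = window
    v_lo, v_hi = v_soma_range
    _, off_at_lo, slope = _offset_affine(cell, v_lo, v_hi)
    v_c = v_lo + (off_min - off_at_lo) / slope
    if not v_lo <= v_c <= v_hi:
        raise ValueError(f"fold voltage {v_c:.2f} mV outside the scanned range")
    return float(v_c)


def vclamp_sweep(cell: DiscretizedCell, v_soma_values, dt: float = 0.05,
                 relax_budget: float = 500.0, dv_tol: float = 1e-6):
    """Quasi-static voltage-clamp sweep: time-domain relaxation per clamp value.

    Each step starts from the previous stationary state (branch following, so
    sweep direction matters).  Returns (stationary axonal voltages, converged
    flags).  Non-convergence within the budget is reported, not fatal: above
    the fold the state leaves the vanished branch and lands on the other one.
    """
    v_soma_values = np.asarray(v_soma_values, dtype=float)
    sod = cell.sodium
    v = None
    m = None
    out = np.empty(v_soma_values.size)
    ok = np.empty(v_soma_values.size, dtype=bool)
    for j, v_c in enumerate(v_soma_values):
        if v is None:
            v = np.full(cell.n_nodes, cell.passive.leak_reversal)
            m = m_inf(cell.passive.leak_reversal, sod)
        v, m, conv = relax_clamped_kernel(
            cell.node_capacitance, cell.node_leak_conductance,
            cell.axial_conductance, cell.passive.leak_reversal,
            cell.na_node, cell.gbar_us, sod.reversal, sod.half_activation,
            sod.slope, sod.activation_time_constant,
            cell.injection_node, float(v_c), dt, v, float(m),
            relax_budget, dv_tol)
        out[j] = v[cell.na_node]
        ok[j] = conv
    return out, ok


def cclamp_ramp(cell: DiscretizedCell, ramp: StimulusTrace,
                detection_threshold: float | None = None,
                max_drift: float = 0.5):
    """Slow current-clamp ramp: the dynamic counterpart of the clamp sweep.

    Integrates the full model without reset, recording somatic and axonal
    voltage; when detection_threshold is given the traces are truncated at
    its first axonal crossing.  Quasi-staticity check: the passive somatic
    drift imposed by the ramp (slope times the DC input resistance) must
    stay below max_drift mV/ms — the regenerative upstroke itself is not a
    violation of slowness.
    """
    from .model import _run_kernel, passive_steady_state

    r_dc = (passive_steady_state(cell, 1.0)[cell.injection_node]
            - passive_steady_state(cell, 0.0)[cell.injection_node])
    slope = np.max(np.abs(np.diff(ramp.samples))) / ramp.dt   # nA/ms
    if slope * r_dc > max_drift:
        raise ValueError("ramp too fast: passive somatic drift "
                         f"{slope * r_dc:.2f} mV/ms exceeds {max_drift}")
    _, _, rec, _, _ = _run_kernel(cell, ramp.samples, ramp.dt, None,
                                  cell.resting_state(),
                                  [cell.injection_node, cell.na_node], 1)
    v_soma, v_axon = rec[0], rec[1]
    if detection_threshold is not None:
        above = np.nonzero(v_axon >= detection_threshold)[0]
        end = above[0] + 1 if above.size else v_axon.size
        v_soma, v_axon = v_soma[:end], v_axon[:end]
    return v_soma, v_axon


def bifurcation_scan(cell: DiscretizedCell, x_na_grid, v_soma_grid,
                     x_tol: float = 0.1) -> BifurcationScan:
    """Equilibrium branches over an (x_Na, somatic voltage) grid, the critical
    distance, and the fold voltage for every x_Na beyond it."""
    x_na_grid = np.asarray(x_na_grid, dtype=float)
    v_soma_grid = np.asarray(v_soma_grid, dtype=float)
    branches = []
    jumps = {}
    v_rng = (float(v_soma_grid[0]), float(v_soma_grid[-1]))
    for x in x_na_grid:
        cx = cell.with_sodium_position(float(x))
        multistable = False
        for v_c in v_soma_grid:
            eq = axonal_equilibria(cx, float(v_c))
            multistable = multistable or eq.n_equilibria >= 3
            for v_a, stable in eq.equilibria:
                branches.append((float(x), float(v_c), v_a, stable))
        if multistable:
            try:
                jumps[float(x)] = fold_voltage(cx, v_rng)
            except ValueError:
                pass
    crit = critical_distance(cell, v_rng,
                             x_bounds=(float(x_na_grid[0]), float(x_na_grid[-1])),
                             x_tol=x_tol)
    return BifurcationScan(x_na_grid=x_na_grid, v_soma_grid=v_soma_grid,
                           branches=branches, critical_distance=crit,
                           jump_voltages=jumps)
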