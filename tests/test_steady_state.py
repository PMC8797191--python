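"""Clamped-soma equilibrium analysis: Thevenin reduction, fold structure,
critical distance, and the dynamic counterparts (sweep, ramp)."""

import numpy as np
import pytest

from axodyn.model import MorphologySpec, build_cell, passive_steady_state
from axodyn.steady_state import (axonal_equilibria, cclamp_ramp,
                                 critical_distance, fold_voltage,
                                 lateral_current_line, vclamp_sweep,
                                 _clamped_passive_solve)
from axodyn.stimulus import slow_ramp

from conftest import coarse_cell


@pytest.fixture(scope="module")
def cell():
    return build_cell()            # default geometry, 1 um grid


@pytest.fixture(scope="module")
def fine_cell_ss():
    return build_cell(MorphologySpec(spatial_step=0.25))


class TestLateralLine:
    def test_offset_vanishes_at_open_circuit_voltage(self, cell):
        g, off = lateral_current_line(cell, -55.0)
        v_open = _clamped_passive_solve(cell, -55.0, 0.0)[cell.na_node]
        assert g * v_open + off == pytest.approx(0.0, abs=1e-12)

    def test_conductance_decreases_with_distance(self, cell):
        gs = [lateral_current_line(cell.with_sodium_position(x), -55.0)[0]
              for x in (5.0, 20.0, 40.0, 80.0)]
        assert np.all(np.diff(gs) < 0)

    def test_thevenin_reproduces_full_solves(self, cell):
        """The affine reduction predicts the clamped passive response to any
        injected current at the sodium node."""
        g, off = lateral_current_line(cell, -58.0)
        for i_test in (-0.3, 0.2, 1.7):
            v = _clamped_passive_solve(cell, -58.0, i_test)[cell.na_node]
            assert g * v + off == pytest.approx(i_test, abs=1e-10)


class TestEquilibria:
    def test_passive_limit_single_root_at_clamped_profile(self, cell):
        passive = coarse_cell(gbar_mult=0.0)
        eq = axonal_equilibria(passive, -55.0)
        expected = _clamped_passive_solve(passive, -55.0, 0.0)[passive.na_node]
        assert eq.n_equilibria == 1
        assert eq.voltages[0] == pytest.approx(expected, abs=1e-6)
        assert eq.equilibria[0][1]     # stable

    def test_small_distance_single_branch(self, cell):
        cx = cell.with_sodium_position(20.0)
        for v_c in np.arange(-60.0, -49.9, 1.0):
            assert axonal_equilibria(cx, v_c).n_equilibria == 1

    def test_x40_has_three_equilibria_in_window(self, cell):
        eq = axonal_equilibria(cell, -57.0)
        assert eq.n_equilibria == 3
        stable = [s for _, s in eq.equilibria]
        assert stable == [True, False, True]

    def test_residuals_are_roots(self, cell):
        eq = axonal_equilibria(cell, -57.0)
        g, off = eq.lateral_line
        from axodyn.model import m_inf
        for v, _ in eq.equilibria:
            i_na = cell.gbar_us * m_inf(v, cell.sodium) * (60.0 - v)
            assert i_na - (g * v + off) == pytest.approx(0.0, abs=1e-9)


class TestCriticalDistance:
    def test_matches_brute_force_scan(self, fine_cell_ss):
        """Counting roots of the current balance over a dense grid of
        lateral-line offsets brackets the bisection result on a 0.5 um grid.
        (Near onset the multistable clamp-voltage window is narrower than
        any practical voltage grid, so the scan runs in offset space; the
        offset is affine in the clamp voltage.)"""
        from axodyn.steady_state import (_net_current, _offset_affine)

        crit = critical_distance(fine_cell_ss)
        grid_v = np.arange(-80.0, 60.0, 0.02)
        multi = []
        x_grid = np.arange(24.0, 32.0, 0.5)
        for x in x_grid:
            cx = fine_cell_ss.with_sodium_position(float(x))
            g_eff, off_lo, slope = _offset_affine(cx, -60.0, -50.0)
            offs = off_lo + slope * np.linspace(0.0, 10.0, 2001)
            fv = _net_current(cx, grid_v, g_eff, 0.0)  # sodium minus g*V part
            phi = fv   # = I_Na - g_eff*V; roots of phi = offset
            signs = np.sign(phi[None, :-1] - offs[:, None]) * \
                np.sign(phi[None, 1:] - offs[:, None])
            multi.append(bool(np.any((signs < 0).sum(axis=1) >= 3)))
        first = x_grid[int(np.argmax(multi))]
        assert first - 0.5 <= crit <= first + 0.5

    def test_conductance_shifts_critical_distance(self, fine_cell_ss):
        """Doubling the sodium peak conductance steepens the sodium I-V curve,
        so the fold appears at a smaller separation (the fold window also
        shifts to lower clamp voltages, hence the wider scanned range)."""
        from dataclasses import replace

        doubled = fine_cell_ss.with_specs(
            sodium=replace(fine_cell_ss.sodium, peak_conductance=2 * 5.23e-9))
        v_rng = (-70.0, -45.0)
        crit1 = critical_distance(fine_cell_ss, v_soma_range=v_rng,
                                  x_bounds=(2.0, 40.0))
        crit2 = critical_distance(doubled, v_soma_range=v_rng,
                                  x_bounds=(2.0, 40.0))
        assert crit2 < crit1

    def test_no_multistability_reported(self):
        passive = coarse_cell(gbar_mult=0.0)
        with pytest.raises(ValueError):
            critical_distance(passive)


class TestClampSweep:
    def test_sweep_matches_stable_branches(self, cell):
        """Time-domain relaxation lands on an algebraic stable branch."""
        vs = np.arange(-60.0, -49.9, 0.5)
        va, ok = vclamp_sweep(cell, vs)
        assert ok.all()
        for v_c, v_a in zip(vs, va):
            eq = axonal_equilibria(cell, float(v_c))
            assert np.min(np.abs(eq.stable_voltages - v_a)) < 0.1

    def test_upward_jump_at_fold(self, cell):
        vs = np.arange(-60.0, -49.9, 0.25)
        va, _ = vclamp_sweep(cell, vs)
        jumps = np.diff(va)
        j = int(np.argmax(jumps))
        assert jumps[j] > 10.0                      # a genuine discontinuity
        assert vs[j + 1] == pytest.approx(fold_voltage(cell), abs=0.3)

    def test_below_critical_distance_continuous(self, cell):
        cx = cell.with_sodium_position(20.0)
        vs = np.arange(-60.0, -49.9, 0.5)
        va, _ = vclamp_sweep(cx, vs)
        assert np.max(np.abs(np.diff(va))) < 2.0


class TestCurrentClampRamp:
    def test_decoupling_is_gradual(self, baseline_cell, baseline_policy):
        ramp = slow_ramp(0.0, 0.25, 4000.0, 0.05)
        v_soma, v_axon = cclamp_ramp(
            baseline_cell, ramp,
            detection_threshold=baseline_policy.detection_threshold)
        assert v_axon[-1] >= baseline_policy.detection_threshold
        pre = v_axon < baseline_policy.detection_threshold
        assert np.max(np.abs(np.diff(v_axon)[pre[:-1]])) < 2.0

    def test_passive_cell_tracks_with_attenuation_only(self):
        passive = coarse_cell(gbar_mult=0.0)
        ramp = slow_ramp(0.0, 0.2, 3000.0, 0.05)
        v_soma, v_axon = cclamp_ramp(passive, ramp)
        # axonal deviation from soma stays bounded by the DC attenuation
        assert np.all(v_axon <= v_soma + 1e-6)
        assert v_soma[-1] - v_axon[-1] < 3.0

    def test_steep_activation_departs_at_half_activation(self):
        """With a near-step activation curve the axon follows the soma until
        V_1/2 and then departs almost instantaneously."""
        cellk = coarse_cell(k_a=0.1)
        ramp = slow_ramp(0.0, 0.3, 4000.0, 0.05)
        v_soma, v_axon = cclamp_ramp(cellk, ramp, detection_threshold=-20.0)
        below = v_axon < -41.0
        assert np.max(np.abs(v_axon[below] - v_soma[below])) < 3.0
        cross = int(np.argmax(v_axon >= -40.0))
        after = v_axon[cross: cross + int(0.5 / 0.05)]
        assert after[-1] - after[0] > 5.0     # departure within 0.5 ms

    def test_too_fast_ramp_rejected(self):
        passive = coarse_cell(gbar_mult=0.0)
        ramp = slow_ramp(0.0, 5.0, 20.0, 0.05)
        with pytest.raises(ValueError):
            cclamp_ramp(passive, ramp)
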