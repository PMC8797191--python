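"""Cable model: discretization, passive oracle, integrator, AP machinery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import axodyn as ax
from axodyn.model import (CellState, MorphologySpec, ResetPolicy, SodiumSpec,
                          SpikeTrain, build_cell, calibrate_thresholds,
                          default_cell, m_inf, measure_reset_latency,
                          passive_steady_state, simulate_trial, step)
from axodyn.stimulus import OUSpec, constant, ou_generate, trial_seed

from conftest import COARSE, DT, coarse_cell


def analytic_input_resistance():
    """Sealed-end two-cylinder cable, DC, injection at the soma middle.

    The left branch is half the soma cylinder; the right branch is the other
    half terminated by the sealed axon (cascade formula for a loaded finite
    cable).  Units: MOhm.
    """
    ra = 150.0 * 1e-2        # MOhm*um
    rm = 30000.0 * 1e2       # MOhm*um^2

    def g_inf_lambda(d):
        lam = math.sqrt(rm * d / (4.0 * ra))
        return (math.pi * d * d / 4.0) / (ra * lam), lam

    g_s, lam_s = g_inf_lambda(50.0)
    g_a, lam_a = g_inf_lambda(1.0)
    g_axon = g_a * math.tanh(600.0 / lam_a)
    t = math.tanh(25.0 / lam_s)
    g_right = g_s * (g_axon + g_s * t) / (g_s + g_axon * t)
    g_left = g_s * t
    return 1.0 / (g_left + g_right)


class TestActivation:
    def test_boltzmann_values(self):
        sod = SodiumSpec()
        assert m_inf(-40.0, sod) == pytest.approx(0.5)
        assert m_inf(-34.0, sod) == pytest.approx(1.0 / (1.0 + math.exp(-1.0)))
        assert m_inf(1000.0, sod) == pytest.approx(1.0)
        assert m_inf(-1000.0, sod) == pytest.approx(0.0, abs=1e-12)

    @given(st.floats(-120, 60), st.floats(-120, 60))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, v1, v2):
        sod = SodiumSpec()
        lo, hi = sorted((v1, v2))
        assert 0.0 < m_inf(lo, sod) < 1.0
        assert m_inf(lo, sod) <= m_inf(hi, sod)

    def test_nonfinite_voltage_rejected(self):
        with pytest.raises(ValueError):
            m_inf(float("nan"))


class TestBuildCell:
    def test_default_node_counts(self):
        cell = default_cell()
        assert cell.n_soma == 50
        assert cell.n_nodes == 650
        assert cell.injection_node == 25
        assert cell.n_soma <= cell.na_node < cell.n_nodes

    def test_soma_membrane_area(self):
        cell = default_cell()
        cm = 0.75e-5    # nF/um^2
        soma_area = cell.node_capacitance[: cell.n_soma].sum() / cm
        assert soma_area == pytest.approx(math.pi * 50.0 * 50.0, rel=1e-9)

    def test_chain_topology_and_positivity(self):
        cell = coarse_cell()
        assert cell.axial_conductance.size == cell.n_nodes - 1
        assert np.all(cell.node_capacitance > 0)
        assert np.all(cell.node_leak_conductance > 0)
        assert np.all(cell.axial_conductance > 0)

    def test_sodium_node_snaps_to_nearest_center(self):
        cell = default_cell(na_position=0.0)
        assert cell.na_node == cell.n_soma      # first axon node
        cell2 = default_cell(na_position=600.0)
        assert cell2.na_node == cell2.n_nodes - 1

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            MorphologySpec(na_position=700.0)
        with pytest.raises(ValueError):
            MorphologySpec(spatial_step=700.0)

    def test_input_resistance_matches_analytic_cable(self):
        cell = default_cell()
        v = passive_steady_state(cell, 0.1)
        r_in = (v[cell.injection_node] + 75.0) / 0.1
        assert r_in == pytest.approx(analytic_input_resistance(), rel=5e-3)

    def test_myelination_override_scales_leak_and_capacitance(self):
        plain = coarse_cell()
        myel = coarse_cell(region_overrides=((60.0, 600.0, 50.0, 1 / 37.5),))
        distal = plain.node_positions - 50.0 > 60.0
        ratio_g = (myel.node_leak_conductance[distal]
                   / plain.node_leak_conductance[distal])
        ratio_c = myel.node_capacitance[distal] / plain.node_capacitance[distal]
        assert np.allclose(ratio_g, 1 / 50.0)
        assert np.allclose(ratio_c, 1 / 37.5)


class TestPassiveSteadyState:
    def test_rest_is_leak_reversal(self):
        v = passive_steady_state(default_cell(), 0.0)
        assert np.allclose(v, -75.0, atol=1e-6)

    def test_superposition(self):
        cell = coarse_cell()
        v0 = passive_steady_state(cell, 0.0)
        v1 = passive_steady_state(cell, 0.05)
        v2 = passive_steady_state(cell, 0.11)
        v12 = passive_steady_state(cell, 0.16)
        assert np.allclose((v1 - v0) + (v2 - v0), v12 - v0, atol=1e-9)


class TestStep:
    def test_passive_fixed_point(self):
        cell = coarse_cell(gbar_mult=0.0)
        s = cell.resting_state()
        for _ in range(20):
            s = step(cell, s, 0.0, DT)
        assert np.allclose(s.voltages, -75.0, atol=1e-9)

    def test_step_response_converges_to_steady_state(self):
        cell = coarse_cell(gbar_mult=0.0)
        target = passive_steady_state(cell, 0.08)
        stim = constant(0.08, DT, int(400.0 * 5 / DT))  # ~18 membrane tau
        traces, _ = simulate_trial(cell, stim, None,
                                   record_nodes=[cell.na_node], burn_in=100.0)
        assert traces[cell.na_node][-1] == pytest.approx(
            target[cell.na_node], abs=1e-6)

    def test_charge_bookkeeping_single_step(self):
        """Injected charge = capacitive charge change + leak loss (implicit)."""
        cell = coarse_cell(gbar_mult=0.0)
        s0 = cell.resting_state()
        i_inj = 0.2
        s1 = step(cell, s0, i_inj, DT)
        dq_cap = float(np.sum(cell.node_capacitance * (s1.voltages - s0.voltages)))
        leak = float(np.sum(cell.node_leak_conductance
                            * (s1.voltages + 75.0))) * DT
        assert dq_cap + leak == pytest.approx(i_inj * DT, rel=1e-9)

    def test_gating_stays_in_unit_interval(self):
        cell = coarse_cell()
        s = CellState(voltages=np.full(cell.n_nodes, -75.0), m=0.5)
        rng = np.random.default_rng(0)
        for _ in range(200):
            s = step(cell, s, float(rng.normal(0, 2.0)), DT)
            assert 0.0 <= s.m <= 1.0


class TestSimulateTrial:
    def test_no_sodium_no_spikes(self):
        """Without the regenerative current the cell cannot reach the AP
        detection voltage from a subthreshold operating point."""
        cell = coarse_cell(gbar_mult=0.0)
        pol = ResetPolicy(detection_threshold=-40.0, reset_threshold=-20.0)
        stim = ou_generate(OUSpec(0.05, 0.02, 5.0, DT, seed=1),
                           int(10000 / DT))
        _, train = simulate_trial(cell, stim, pol, burn_in=500.0)
        assert train.n_spikes == 0

    def test_constant_current_fires_periodically(self, baseline_cell,
                                                 baseline_policy):
        from axodyn.model import target_rate_current
        from axodyn.calibration import rate_cv

        i5 = target_rate_current(baseline_cell, baseline_policy, 5.0, DT)
        stim = constant(i5, DT, int(20500 / DT))
        _, train = simulate_trial(baseline_cell, stim, baseline_policy)
        assert train.n_spikes == pytest.approx(100, abs=5)
        _, cv = rate_cv([train])
        assert cv < 0.02

    def test_spike_train_invariants(self):
        with pytest.raises(ValueError):
            SpikeTrain(spike_times=np.array([700.0, 600.0]),
                       trial_duration=20000.0, burn_in=500.0)
        with pytest.raises(ValueError):
            SpikeTrain(spike_times=np.array([100.0]),
                       trial_duration=20000.0, burn_in=500.0)


class TestResetCalibration:
    def test_threshold_ordering_and_latency(self, baseline_cell,
                                            baseline_policy):
        pol = baseline_policy
        assert pol.detection_threshold < pol.reset_threshold
        assert pol.detection_threshold > -55.0   # above subthreshold range
        lat = measure_reset_latency(baseline_cell, pol, 5.0, DT)
        assert lat == pytest.approx(2.0, abs=0.1)

    def test_steep_activation_variant_calibrates(self):
        cell = coarse_cell(k_a=0.1)
        pol = calibrate_thresholds(cell, 5.0, dt=DT)
        assert np.isfinite(pol.detection_threshold)
        assert np.isfinite(pol.reset_threshold)
        assert pol.detection_threshold < pol.reset_threshold

    def test_non_excitable_configuration_reported(self):
        cell = coarse_cell(gbar_mult=0.0)
        with pytest.raises(RuntimeError):
            calibrate_thresholds(cell, 5.0, dt=DT)


class TestSelfConvergence:
    def test_spike_times_converge_with_dt_and_dx(self):
        """Halving dt and dx moves each spike by < 0.5 ms (fixed OU seed)."""
        from axodyn.stimulus import StimulusTrace

        pol = ResetPolicy(detection_threshold=-34.8, reset_threshold=-18.9)
        n_ms = 8000.0
        fine = ou_generate(OUSpec(0.015, 0.048, 5.0, 0.0125, seed=99),
                           int(round(n_ms / 0.0125)))
        # the same continuous noise path restricted to the coarse step
        coarse_samples = fine.samples.reshape(-1, 2).mean(axis=1)
        stims = {0.0125: fine,
                 0.025: StimulusTrace(coarse_samples, 0.025, "ou",
                                      fine.generator_params)}
        trains = []
        for dt, dx in ((0.025, 1.0), (0.0125, 0.5)):
            cell = build_cell(MorphologySpec(spatial_step=dx))
            _, train = simulate_trial(cell, stims[dt], pol, burn_in=500.0)
            trains.append(train.spike_times)
        a, b = trains
        assert min(len(a), len(b)) >= 10
        from conftest import matched_spike_fraction

        assert matched_spike_fraction(a, b, tol=0.5) >= 0.9
        assert matched_spike_fraction(b, a, tol=0.5) >= 0.9
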