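# axodyn

Population coding speed of a ball-and-stick neuron model: simulation and
dynamic-gain analysis of axo-somatic compartmentalization.

Cortical neuron populations can track shared input fluctuations up to
hundreds of Hz. One candidate explanation is *resistive coupling*: the
action potential initiates in the axon initial segment (AIS), electrically
separated from the soma by the axial resistance of the proximal axon.
`axodyn` implements the idealized two-cylinder model used to test this
hypothesis — a cylindrical soma (50 μm) joined to a thin axon (1 μm × 600
μm) with a single sodium point conductance at distance `x_Na` from the soma
— and the full analysis tool-chain around it:

- **Cable simulation** (`axodyn.model`): backward-Euler integration of the
  discretized cable equation with a Boltzmann-activated sodium point
  conductance (`m_inf(V) = 1/(1+exp((V_1/2−V)/k_a))`, τ_m = 0.1 ms, no
  inactivation), AP detection at the point of maximal axonal dV/dt, and a
  calibrated forced reset 2 ms after detection.
- **Stimulus synthesis** (`axodyn.stimulus`): exact-discretization
  Ornstein–Uhlenbeck currents (mean μ, std σ, correlation time τ),
  sinusoids, ramps, and an inhomogeneous-Poisson fixture with a known
  imposed transfer function for estimator validation.
- **Operating-point calibration** (`axodyn.calibration`): nested search for
  the (μ, σ) that hold a model variant at a prescribed firing rate and
  ISI coefficient of variation (default ν = 5 ± 0.25 Hz, CV = 0.85 ± 0.05),
  so different variants are compared at equivalent operating points.
- **Dynamic gain estimation** (`axodyn.gain`): the linear response
  L(f) = F[⟨ν⟩·STA_I] / P(f) from spike-triggered average currents
  (800 ms window), with Gaussian filter-bank denoising, a cyclic-shift
  surrogate significance threshold, bootstrap confidence intervals, and
  factor-2 cutoff-frequency extraction. Statsmodels-style interface:
  `DynamicGain(currents, spikes, ou, config).fit()` returns a result object
  with `summary()`.
- **Steady-state bifurcation analysis** (`axodyn.steady_state`): Thevenin
  reduction of the clamped passive cable at the sodium node, the
  three-equilibrium fold structure, the critical AIS distance, and
  quasi-static voltage-clamp/current-clamp sweeps.
- **Impedance and phase planes** (`axodyn.impedance`): soma→AIS transfer
  impedance (sinusoidal and OU cross-spectral routes) and AP phase plots
  aligned at the pre-upstroke dV/dt minimum.
- **Experiment presets and CLI** (`axodyn.experiments`, `axodyn` command):
  figure-level parameter scans (AIS position, sodium conductance and
  voltage sensitivity, input correlation time, axial resistivity, soma
  size, myelination) at desk scale, with `--paper-scale` switches.

## Worked example

```python
import axodyn as ax
from axodyn.model import MorphologySpec, build_cell, calibrate_thresholds
from axodyn.steady_state import critical_distance, fold_voltage

# steady-state compartmentalization analysis (seconds, deterministic)
cell = build_cell(MorphologySpec(spatial_step=0.25))
print(critical_distance(cell))   # 27.52  (μm: onset of axonal bistability)
print(fold_voltage(build_cell()))  # -55.84 (mV: clamped somatic voltage at
                                   #         which the axonal voltage jumps)

# dynamic gain at the standard operating point (a few minutes, desk scale)
cell = build_cell(MorphologySpec(spatial_step=4.0, soma_spatial_step=10.0))
policy = calibrate_thresholds(cell, target_rate=5.0, dt=0.05)
op = ax.find_operating_point(cell, policy, ax.WorkingPoint(), tau=5.0, seed=11)
res = ax.run_gain_pipeline(cell, policy, op.mu, op.sigma, tau=5.0,
                           config=ax.desk_config(n_trials=300), seed=5)
print(res.summary())
```

The summary printed by the last call:

```
Dynamic gain estimate
=====================
trials                300
spikes (in STA)       29093
mean rate                4.944 Hz
mean input current      0.0151 nA
OU sigma / tau        0.0479 nA / 5.0 ms
frequency band        1.25 - 992.9 Hz (59 centers)
significant band      1.25 - 279.8 Hz
low-frequency gain      336.72 Hz/nA
cutoff frequency         19.13 Hz
high-frequency slope    -0.754 (log-log)
```

The low-frequency gain equals the static gain dν/dμ at the operating point;
the gain then decays with a log-log slope near −1, so this model variant is
a low-pass encoder with a bandwidth of tens of Hz. Raising the voltage
sensitivity of the sodium activation curve (`SodiumSpec(slope=0.1)`) makes
the same pipeline report a near-flat gain out to several hundred Hz —
ultrafast coding — while moving the AIS or scaling the conductance changes
the curve only weakly.

The same computations are available from the shell:

```sh
axodyn bifurcate --out out/          # critical distance + clamp sweep
axodyn gain --n-trials 300 --out out/
axodyn experiment --preset fig2 --out out/
```

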