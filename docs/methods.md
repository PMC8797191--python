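# Methods

## Model

The cell is a two-cylinder (ball-and-stick) cable: a somatic cylinder of
equal length and diameter (default 50 μm, matching the membrane area of a
50 μm sphere) joined to a sealed-end axon (1 μm diameter, 600 μm long).
Passive properties are uniform: axial resistivity R_a = 150 Ω·cm, specific
capacitance c_m = 0.75 μF/cm², specific membrane resistance
R_m = 30 000 Ω·cm², leak reversal E_L = −75 mV (membrane time constant
22.5 ms). The only nonlinearity is a sodium *point* conductance at distance
x_Na from the soma–axon junction:

    I_Na = ḡ_Na · m · (E_Na − V),   τ_m dm/dt = m_∞(V) − m,
    m_∞(V) = 1 / (1 + exp((V_1/2 − V)/k_a)),

with ḡ_Na = 5.23 nS (absolute, not a density), E_Na = 60 mV,
V_1/2 = −40 mV, k_a = 6 mV, τ_m = 0.1 ms, and no inactivation. Stimulus
current enters at the middle of the soma. Because nothing repolarizes the
cell, each AP is terminated by a forced global reset of all node voltages
(to E_L by default; a −90 mV variant keeps type-1 excitability when the
sodium conductance is scaled up severalfold). The gating variable resets to
m_∞ of the reset voltage; in the −90 mV variant this means m_∞(−90 mV),
keeping the reset a consistent state reset.

### Discretization and integration

The cable is discretized into node-centered segments (default 1 μm; the
soma may use its own step, e.g. 1000 μm for centimeter-scale somata).
Per-node membrane area is π·d·Δx; axial edges carry (π d²/4)/(R_a Δx), and
the junction edge is the series combination of the two adjacent
half-segments. The sodium conductance attaches to the axonal node nearest
x_Na (consistent with a δ-function conductance; x_Na = 0 maps to the first
axon node). Internal units are mV/ms/nA/μS/nF/μm, which keeps the linear
systems well-scaled.

Time stepping is backward Euler with staggered gating: m relaxes
exponentially toward m_∞ evaluated at the pre-step sodium-node voltage,
then the voltage system is solved implicitly with g_Na·m held fixed within
the step. The constant tridiagonal factor is precomputed and the rank-one
sodium term folded in per step by the Sherman–Morrison identity, so one
step costs one forward/backward sweep. Exactness checks: the passive model
is a machine-precision fixed point at E_L; an implicit step conserves
charge identically; the time-domain step response converges to the direct
linear solve of the stationary system.

AP detection uses the axonal voltage at the point of maximal mean upstroke
dV/dt, measured on a constant-current pilot run firing at the target rate;
spike times are linearly interpolated between samples. The reset threshold
is then bisected until the mean detection-to-reset latency is
2.0 ± 0.1 ms, re-finding the target-rate current whenever the threshold
moves it (latency is verified at the 5 Hz constant current, the same
procedure the test suite uses). Excitability is established against the
passive prediction: a configuration only counts as spiking if its free
trajectory exceeds the passive steady-state voltage by more than 5 mV,
which correctly rejects passive depolarization at large drive.

### Default problem sizes

The reference conditions are 20 000 trials of 20 s (0.5 s burn-in) at
Δt = 25 μs, Δx = 1 μm. Desk-scale runs — the package defaults for tests,
the acceptance script and the experiment presets — use 300–400 trials at
Δt = 50 μs with a 4 μm axonal and 10 μm somatic grid. This coarsening was
validated by self-convergence: with a fixed OU sample path, halving
Δt and Δx moves individual spike times by < 0.5 ms, and the desk-scale
gain curve agrees with the reference-grid curve to within ~4% below
100 Hz. Paper-scale runs remain available via configuration
(`--paper-scale`); they are cluster-sized jobs.

## Stimuli

OU currents use the exact AR(1) discretization
I_{k+1} = μ + (I_k − μ)e^{−Δt/τ} + σ√(1−e^{−2Δt/τ}) ξ_k with a stationary
initial sample, so mean, variance and autocorrelation are unbiased at any
Δt; the analytic power spectral density is P(f) = 2τσ²/(1+(2πτf)²).
Trials are seeded by a counter scheme (root seed × trial index through
`numpy.random.SeedSequence`), making results independent of execution
order.

The estimator-validation fixture draws inhomogeneous-Poisson spike trains
with rate ν(t) = ν₀ + (l ∗ ΔI)(t) for a chosen transfer function L (the
Fourier transform of l), via per-bin Bernoulli thinning. By construction
the true dynamic gain is |L(f)|, so the full estimation pipeline can be
checked for coverage and bias without the neuron simulator. Negative rates
are clipped at zero and more than 0.1% clipped samples is an error
(modulation too deep).

## Operating-point calibration

Gain curves are only comparable at matched operating points (rate ν, ISI
coefficient of variation CV). At fixed rate the CV is governed mainly by σ
and the rate by μ, so the search nests a bisection on μ (rate) inside a
secant iteration on σ (CV). Each evaluation simulates ≥ 200 s; the
returned point is verified on held-out seeds against the tolerances
(ν = 5 ± 0.25 Hz, CV = 0.85 ± 0.05 by default; a fixed-σ mode reduces to
the μ bisection). The initial σ guess scales as τ^{−0.7}, reflecting that
slow noise spreads ISIs more effectively. Calibrations are cached to JSON
keyed by a hash of (cell, policy, working point, τ). Trend-level
experiments may use the documented looser band (±0.5 Hz, ±0.1 CV) with
shorter pilots; all headline numbers use the standard band.

## Dynamic gain estimation

The linear response is L(f) = F[C_Iν]/F[C_II] with
C_Iν(τ) = ⟨ν⟩·STA_I(τ): the zero-average spike-triggered average current
in an 800 ms window centered on the spike, times the mean rate. Currents
are decimated to 0.1 ms by boxcar averaging and spikes aligned to the
nearest decimated sample (phase error < 0.05 cycles at 1 kHz); windows
clipped at trace edges are excluded. The denominator is the analytic OU
PSD by default (an `empirical` mode uses the windowed input
autocorrelation spectrum instead; the two agree within 10% over the
mid-band on fixture data).

Denoising uses a bank of log-spaced Gaussian filters (20 centers/decade
from 1.25 Hz to 1 kHz, σ_f = 0.25·f_c, applied jointly to real and
imaginary parts; both geometry parameters are recorded in all outputs).
The bank is applied to the complex response L(f) = numerator/PSD on the
uniform FFT grid, *not* to the numerator: the numerator falls like f⁻³ at
high frequency and Gaussian-averaging a convex power law biases the
filtered values upward by tens of percent at this fractional width,
which the fixture exposes directly (confidence-interval coverage collapses).
Smoothing the ~f⁻¹ response removes the bias; fixture coverage is then
nominal.

Significance: the full pipeline is re-run on surrogates in which all spike
times of a trial are cyclically shifted by one random interval (1–19 s for
20 s trials, i.e. 5–95% of the trial length in general); the pointwise
95th percentile over 500 surrogates is the threshold, and downstream
consumers mask gain values below it. Confidence intervals: trial-group
STAs (400 groups of 50 at reference scale; per-trial groups when fewer
trials are available, since intermediate groupings of only a handful of
groups give degenerate intervals) are bootstrap-resampled 1000 times with
spike-count weighting, and the 2.5/97.5 percentiles of the resulting gain
curves are reported.

The cutoff frequency is the smallest frequency at which the gain has
decayed to half its reference value — the gain at the lowest *significant*
frequency — found by log-linear interpolation and required to stay below
half for the next two grid points. For resonant curves (τ = 50 ms shows a
slight enhancement below the cutoff) a peak-referenced variant is
available by flag; for the monotone curves analyzed here the two coincide.
The high-frequency decay exponent is the straight-line slope of log₁₀ gain
vs log₁₀ f over the significant part of 30–200 Hz.

Estimator validation (all in the test suite): on fixture data the true
|L(f)| lies inside the bootstrap interval at ≥ 90% of significant
frequencies; input-independent spikes exceed the significance curve at
≤ 10% of frequencies; the threshold scales as 1/√(spike count) and the
interval width as 1/√(trials); scaling all currents by c scales the gain
by exactly 1/c; and — on the neuron itself — the STA-based gain at
2–40 Hz equals the gain measured directly with small sinusoidal probes,
and the low-frequency gain equals the finite-difference static gain
dν/dμ.

## Steady-state bifurcation analysis

With the somatic voltage clamped (Dirichlet row at the injection node),
everything except the sodium conductance is linear, so the cable seen from
the sodium node reduces exactly (two linear solves) to a Thevenin one-port:
the "lateral" current leaving the node is I_lat(V_A) = g_eff(V_A − V_open).
This convention includes the sodium node's own local leak, which makes the
intersection condition I_Na(V_A) = I_lat(V_A) exactly the stationarity
condition of the full clamped model. Writing φ(V) = I_Na(V) − g_eff·V,
three equilibria exist precisely when the offset current lies between the
two local extrema of φ (the voltages where the sodium I–V slope equals
g_eff), and the offset is affine in the clamp voltage — so multistability
windows, the critical x_Na (bisection to 0.1 μm, bounded below by the grid
since the sodium site snaps to the nearest node) and the fold voltage of
the upward sweep are computed without gridding over clamp voltages.
Near the critical distance the multistable clamp-voltage window is
narrower than any practical grid, which is why the window criterion is
evaluated in offset space. Stability follows from the sign of the net
current's slope at the root (the rest of the system is linear and stable).
The quasi-static time-domain sweep (0.25 mV steps, relaxation to
|dV/dt| < 10⁻⁶ mV/ms within 500 ms per step) reproduces the stable
branches to < 10⁻⁴ mV and exhibits the hysteretic jump at the fold; the
current-clamp ramp (with a < 0.5 mV/ms quasi-staticity check) shows the
gradual decoupling that replaces the jump in the unclamped cell.

With default parameters the critical distance computes to 27.5 μm on a
0.25 μm grid and the x_Na = 40 μm fold sits at −55.8 to −55.9 mV
(sweep-step dependent within 0.1 mV).

## Transfer impedance and phase plots

The passive soma→AIS transfer impedance is measured two independent ways:
sinusoidal probing (≥ 5 transient cycles discarded, ≥ 10 cycles measured,
amplitude ratio at the stimulus bin) and Welch cross-spectral estimation
under OU drive (|S_IV|/S_II); they agree within 5% over 2–500 Hz and both
converge to the algebraic DC transfer resistance. Phase plots use central
differences at the recording step (0.025–0.05 ms) with no smoothing;
alignment translates the last local minimum of dV/dt before the fastest
upstroke to the origin.

## Known limitations

- The model omits sodium inactivation, potassium currents and dendrites by
  design; the forced reset makes ISI statistics near the reset slightly
  artificial, which is why gain comparisons are made at matched (ν, CV).
- The synthetic conditions probe current-driven operating points only; real
  synaptic input changes conductance as well as current, so passing tests
  bound estimator behavior, not biological realism.
- Desk-scale trial counts leave the significant band ending near 200–300 Hz
  (threshold scales with 1/√spikes); reference-scale runs extend it.
- The measured baseline cutoff is ~19–20 Hz by the factor-2/low-frequency-
  reference definition. It is insensitive to the operating point within the
  calibrated band, grid-converged, and consistent between the STA estimator
  and direct sinusoidal probing; smaller AIS distances give proportionally
  lower values (~15 Hz at x_Na = 0).
- The filter-bank geometry (centers/decade, fractional width) is a
  reporting-relevant choice: very sharp spectral features are broadened by
  the constant-relative-width smoothing.
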