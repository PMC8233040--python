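# Methods

This note documents the model implemented in `hd2speed`, the choices made
where the design was genuinely open, and what the synthetic study
conditions do and do not establish about real data.

## Circuit model

The simulated circuit is feedforward: an ensemble of N anterior-thalamic
head-direction (HD) cells, conditionally independent given the heading
trajectory, drives a single retrosplenial low-rheobase (LR) readout
through one synapse per cell.

**Trajectory.** The heading θ(t) is stored unwrapped on a uniform grid
(default dt = 1 ms — fine enough to resolve the 4 ms refractory period and
all synaptic time constants).  Angular velocity uses the centered
difference on the unwrapped angle, with one-sided differences at the two
boundary samples so the series stays full length for lag analysis.
Unwrapping before differentiation and interpolation avoids spurious 2π
jumps at the circular seam.  Internal units are radians, ms, and rad/s
throughout; conversion to degrees is left to display code.

**Synthetic sessions.** Real head-tracking tables (time/angle text files)
are supported directly; the default inputs are synthetic sessions that
emulate one.  Angular velocity follows a stationary Ornstein–Uhlenbeck
process discretised exactly on a 40 Hz "raw tracking" grid, integrated to
a heading and linearly interpolated to the fine grid — the same low-rate
interpolation a real tracking recording undergoes.  Defaults:
relaxation time τ_ω = 100 ms and stationary SD σ_ω = 3.0 rad/s
(≈ 170 deg/s).  Rationale: rodent head turns are ballistic on the ~100 ms
scale and angular speeds span quiescence to several rad/s; these
statistics also place the circuit in the operating regime reported with
real trajectories, where the readout's optimal lag at the population-mean
anticipatory interval falls inside the −70…+70 ms analysis window.  What
the OU process does *not* emulate: bimodal quiescent/moving bout
structure, systematic turning biases, and tracking artifacts.  Conclusions
drawn from passing tests are therefore about the mechanism (depression →
speed code), not about quantitative lags on any particular dataset.

**HD cells.** Tuning is the circular Gaussian
f(θ) = (f_max − f_bg)·e^{ε(cos θ − 1)} + f_bg.  Per-cell parameters are
drawn from shifted/scaled Beta distributions.  The exact population table
used in the original fits is not reproduced here; the defaults are
provisional and config-exposed, chosen to match anterodorsal-thalamus HD
statistics: background rates ~0.5–10 Hz (mean ≈ 3), peak rates 15–75 Hz
(mean ≈ 39), concentration ε ∈ [1, 8] (half-widths of several tens of
degrees), and anticipatory intervals 0–100 ms with mean 50 ms.  Joint
draws violating f_max ≥ f_bg are redrawn (the defaults cannot produce
them, but the guard keeps the tuning formula interpretable under any
config).  Anticipation is applied per cell through the effective
trajectory θ_A = θ + (A/1000)·ω with the velocity computed once and
shared.

**Spiking.** Inhomogeneous Poisson by thinning against the per-cell peak
rate, with an absolute dead time: candidates within 4 ms of the last
accepted spike are rejected outright, so a constant-rate train is renewal
with rate λ/(1 + λ·0.004).  One master seed spawns an independent stream
per cell, making results independent of iteration order and population
size.

**Synapses.** Tsodyks–Markram state (x, u, g) with exact closed-form
relaxation between spikes and the standard jump relations at spikes; the
event-driven trajectories carry no integration error (verified against
fixed-step RK4 at dt = 0.01 ms to < 1e-6).  The fitted thalamocortical
parameters are τ_d = 270 ms, τ_f = 40 ms, U = 0.28 — moderately
depressing at 10 Hz, more strongly at 40 Hz.  The conductance decay τ_g
is not constrained by the amplitude fits; default 10 ms (fast AMPA-like),
config-exposed, and the readout lag shifts by roughly the change in τ_g
(plus the membrane constant below), so lag results should be read with
that sensitivity in mind.  The non-depressing control is an exponential
synapse whose fixed jump equals the depressing synapse's first-pulse
response (weight·U), so both modes deliver identical drive from rest.

**Parameter fitting.** `fit_tm` grid-searches (τ_d, τ_f, U) exhaustively
(τ_d 10–1000 ms step 10, τ_f 5–500 ms step 5, U 0.02–0.98 step 0.02),
minimising the summed squared error between model and data *normalized*
amplitudes (stimulus n / stimulus 1); ties break to the lexicographically
smallest triple, and the weight is recovered from the raw first amplitude
(first release from rest = U).  The measured amplitude table is not
shipped with the package; tests and the acceptance script exercise the
fitter on trains synthesized from the fitted parameter set (a
parameter-recovery check with a synthetic stand-in).

**Readout.** The reference readout is rate-based: the per-synapse-
normalized summed conductance is low-pass filtered with membrane constant
τ_m and mapped affinely to Hz.  Correlation and MI are invariant to the
affine map, so gain/baseline only set the plotted scale (defaults put
desk-scale output in the tens of Hz).  τ_m defaults to 35 ms: a delay
budget argument — depression dynamics contribute ~60 ms of effective lag
under the default trajectory statistics, plus τ_g = 10 ms, minus the
50 ms population-mean anticipation — lands the optimal lag at ≈ 55 ms,
inside the analysis window, while providing enough temporal averaging
that the desk-scale Poisson noise does not swamp the speed signal.  A
conductance-based spiking point neuron (Wang–Buzsáki-style Na⁺/K⁺
kinetics plus a slow non-inactivating K⁺ conductance standing in for the
Kv1.1 current, driven via g·(E_syn − V)) is provided as a secondary
readout; tests check it agrees with the rate readout on the sign and
ordering of the coding metrics, not on exact values.  Firing rates from
spikes use an edge-corrected Gaussian kernel (default SD 50 ms).

## Coding analysis

Similarity between series x_t, y_t is evaluated as M(x_t, y_{t−l}) over a
lag grid; with x the readout rate and y the head speed, positive optimal
lag means the rate tracks past speed.  Measures: Pearson correlation and
plug-in mutual information on equal-width 40-bin discretizations of each
overlap segment.  The default grid spans −70…+70 ms in 5 ms steps; 5 ms
matches the empirical argmax precision of both similarity curves at desk
scale (their peaks are flat on the ~10 ms scale, so a finer grid
oversamples).  Undefined values (zero-variance or short overlaps) are NaN
markers, never silent zeros; argmax ties break toward the smallest |lag|,
then the negative lag.  The fixed-ATI sweep uses a wider ±150 ms grid so
the zero-anticipation optimum is measured rather than clipped at the
window edge.  "Correlation with head direction" is the circular–linear
coefficient (multiple correlation of the rate on cos θ, sin θ), since a
Pearson correlation with a raw angle depends on the seam; MI with binned
wrapped direction is the seam-free cross-check.

**Preferred-angle heterogeneity.** Nonuniform PA densities are built by
exponentiating a Brownian bridge (the bridge is a log-density — this
guarantees positivity and 2π-periodicity; clipping or offsetting a bridge
were the alternatives) and normalizing; `roughness` is the bridge SD, and
sampling uses inverse-transform of the circular CDF.  Heterogeneity is
the circular 1-Wasserstein distance from uniform with arc-length ground
metric, computed as min_c ∫|F_p − F_u − c| dθ at the weighted median c.
The population-tradeoff experiment draws roughness uniformly on [0, 2.5],
which spreads WD over ≈ 0–0.6 rad.

## Mean-field reduction

The continuum model evolves a depression field
∂x/∂t = (1 − x)/τ_d − U·x·f(θ − θ_A(t)) over the PA circle (facilitation
dropped: τ_f ≪ τ_d at the fitted point) with drive
D(t) = ∫ U·x·f dθ, low-pass filtered with τ_post.  Integration is
operator-split per step — exact relaxation toward 1, then exact
exponential depletion at the local rate — on a 256-point θ grid (drive
changes < 0.1% on doubling).  It is used to verify: (i) steady drive
grows with rotation speed, (ii) the low-speed growth is quadratic
(log-log exponent ≈ 2, concave-up tuning), and (iii) anticipation
walks the drive–speed lag toward zero.  A matched stochastic ensemble
(depression-only synapses, shared tuning, no refractory) reproduces the
continuum release flux within Monte Carlo error.

## Study conditions and problem sizes

Desk-scale defaults — 120 s sessions, 1000 HD cells for the speed-coding
experiment (robustness re-checked at 2500), 50 LR cells × 60 s × 500
inputs for the population tradeoff — reproduce all qualitative orderings
in minutes on one CPU; full-scale profiles (7500 cells, long sessions)
are plain config changes.  At desk scale the Poisson spike noise is the
main limiter: the noise-free mean-field ceiling on the speed correlation
is ≈ 0.7–0.75 under the default trajectory statistics, the 1000-cell
spiking run reaches ≈ 0.45–0.55, and larger ensembles close the gap.

## Known limitations

- HD cells are conditionally independent given the trajectory: no
  attractor dynamics, bursting, or adaptation beyond the dead time.
- The morphologically detailed LR neuron is replaced by point readouts;
  dendritic placement effects and feedforward inhibition are out of scope.
- Beta-distribution defaults for the HD population are provisional
  (see above) and should be recalibrated against a population table
  before quantitative comparisons with recordings.
- The exact optimal-lag value depends on the unprinted readout constants
  (τ_g, τ_m, kernel SD) and on trajectory statistics; only orderings and
  window-level statements are asserted by the test suite.
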