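# hd2speed

**Angular head-speed coding from depressing thalamocortical synapses.**

Anterior-thalamic head-direction (HD) cells tell the brain *which way* the
head points, not *how fast* it turns.  Yet their main cortical targets —
the small, hyperexcitable low-rheobase (LR) pyramidal cells of superficial
granular retrosplenial cortex — receive this input through strongly
*depressing* synapses.  `hd2speed` simulates that circuit and shows how
short-term synaptic depression converts a purely directional population
code into an angular head-speed code in the postsynaptic firing rate, how
anticipatory firing of HD cells sharpens that code, and how nonuniform
preferred-angle pools let single LR cells trade speed precision for
directional selectivity.

The package is aimed at computational neuroscientists studying
head-direction circuits, short-term plasticity, or rate-of-change
computations in feedforward networks.

## The model

An HD cell with preferred angle (PA) θ₀ fires at rate

    f(θ) = (f_max − f_bg) · exp(ε (cos(θ₀ − θ) − 1)) + f_bg

as a function of heading θ, with background rate `f_bg`, peak rate
`f_max` and concentration ε drawn per cell from Beta distributions.
Anticipatory firing with time interval A transforms the heading each cell
experiences into θ_A(t) = θ(t) + A·θ̇(t) — equivalently, at angular
velocity ω the cell's PA shifts to θ₀ − ωA.  Spikes are inhomogeneous
Poisson with a 4 ms absolute refractory period.

Each spike drives a Tsodyks–Markram synapse with state (x, u, g) —
vesicle-pool fraction, release probability, conductance:

    dx/dt = (1 − x)/τ_d      u⁺ = u⁻ + U(1 − u⁻)
    du/dt = −u/τ_f           release = u⁺ x⁻,   x⁺ = x⁻(1 − u⁺)
    dg/dt = −g/τ_g           g⁺ = g⁻ + A_w · release

with the depression-dominated parameter set τ_d = 270 ms, τ_f = 40 ms,
U = 0.28 obtained by exhaustive least-squares fitting to 10 Hz
thalamocortical EPSP amplitude trains.  The summed ensemble conductance is
low-pass filtered into an LR firing rate (a conductance-based spiking
point neuron is available as a cross-check).  Coding is quantified by
lagged Pearson correlation and lagged mutual information (40-bin plug-in
estimator) between the readout rate and angular head speed or direction,
over lags spanning −70…+70 ms.

A mean-field reduction replaces the spiking ensemble with a depression
field x(θ, t) over the PA continuum and verifies the analytical claims:
steady drive grows quadratically with rotation speed at low speeds, and
anticipation compensates the integration lag.

## Worked example

```python
import numpy as np
import hd2speed as h
from hd2speed.experiments import ExperimentConfig

res = h.run_speed_coding(ExperimentConfig(seed=3))  # 120 s, 1000 HD cells
print(res.corr_depressing.max_value)                          # 0.516
print(res.corr_depressing.optimal_lag)                        # 55.0
print(float(np.nanmax(np.abs(res.corr_nondepressing.values))))  # 0.051
print(res.mi_depressing.optimal_lag)                          # 60.0
```

The depressing-synapse readout correlates strongly (≈ 0.52) with angular
head speed ≈ 55 ms in the past — the residual synaptic/membrane
integration delay after anticipation — and mutual information identifies
the same optimal lag to within one 5 ms grid step.  The identical
ensemble wired through non-depressing control synapses is uncorrelated
with speed (≈ 0.05): the speed code is created de novo by synaptic
depression.

The `examples/` directory holds one short narrative script per capability
(trajectory synthesis, synapse fitting, speed coding, the anticipation
sweep, the population tradeoff, the mean-field reduction); each prints the
numbers it computes and a line on what they mean.  A thin CLI wraps the
most common entry points:

```bash
hd2speed synth-trajectory --duration 60 --seed 0 --out traj.csv
hd2speed fit-tm --amps amps.csv --out fit.json
hd2speed run ati-sweep --seed 11 --out sweep.csv
```

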