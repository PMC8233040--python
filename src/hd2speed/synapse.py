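"""Tsodyks–Markram short-term synaptic plasticity.

State triple (x, u, g): vesicle-pool fraction, release probability, and
synaptic conductance.  Between presynaptic spikes the variables relax
linearly,

    dx/dt = (1 − x)/τ_d,   du/dt = −u/τ_f,   dg/dt = −g/τ_g,

and each spike applies the jump relations u⁺ = u⁻ + U(1 − u⁻),
release = u⁺x⁻, x⁺ = x⁻(1 − u⁺), g⁺ = g⁻ + A·release, with synaptic
weight A.  τ_d ≫ τ_f gives depression-dominated dynamics; the fitted
thalamocortical parameters here are τ_d = 270 ms, τ_f = 40 ms, U = 0.28.
The non-depressing control is a plain exponential synapse.

The between-spike relaxations are exact (closed-form), so event-driven
trajectories carry no integration error.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._kernels import tm_release_train
from .ensemble import SpikeTrain

#: Parameters fitted to 10 Hz thalamocortical (ADAV -> LR) EPSP trains.
FITTED_TAU_D = 270.0
FITTED_TAU_F = 40.0
FITTED_U = 0.28


@dataclass(frozen=True)
class TMParams:
    """TM synapse constants.  Times in ms; U dimensionless in (0, 1];
    weight in conductance units (µmho in the original mechanism)."""

    tau_d: float = FITTED_TAU_D
    tau_f: float = FITTED_TAU_F
    tau_g: float = 10.0
    U: float = FITTED_U
    weight: float = 1.0

    def __post_init__(self) -> None:
        if min(self.tau_d, self.tau_f, self.tau_g, self.weight) <= 0:
            raise ValueError("tau_d, tau_f, tau_g and weight must be positive")
        if not (0.0 < self.U <= 1.0):
            raise ValueError("U must lie in (0, 1]")


@dataclass(frozen=True)
class TMState:
    """Dynamical state of one synapse at time t_last."""

    x: float = 1.0
    u: float = 0.0
    g: float = 0.0
    t_last: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.x <= 1.0 and 0.0 <= self.u <= 1.0 and self.g >= 0.0):
            raise ValueError("state out of bounds: need x, u in [0,1] and g >= 0")


@dataclass(frozen=True)
class PulseAmplitudes:
    """Per-pulse synaptic response amplitudes of a periodic train."""

    amps: np.ndarray
    isi: float

    def __post_init__(self) -> None:
        amps = np.asarray(self.amps, dtype=float)
        if amps.size and (np.any(amps < 0) or amps[0] <= 0):
            raise ValueError("amplitudes must be nonnegative with positive first pulse")
        object.__setattr__(self, "amps", amps)

    @property
    def normalized(self) -> np.ndarray:
        """Amplitudes divided by the first (stimulus n / stimulus 1)."""
        return self.amps / self.amps[0]


def tm_relax(state: TMState, dt: float, params: TMParams) -> TMState:
    """Closed-form relaxation over a spike-free interval of dt ms."""
    if dt < 0:
        raise ValueError("dt must be nonnegative")
    return TMState(
        x=1.0 - (1.0 - state.x) * np.exp(-dt / params.tau_d),
        u=state.u * np.exp(-dt / params.tau_f),
        g=state.g * np.exp(-dt / params.tau_g),
        t_last=state.t_last + dt,
    )


def tm_spike(state: TMState, params: TMParams) -> tuple[TMState, float]:
    """Apply the spike jump; returns (new state, release fraction u⁺x⁻)."""
    u_plus = state.u + params.U * (1.0 - state.u)
    release = u_plus * state.x
    new = TMState(
        x=state.x * (1.0 - u_plus),
        u=u_plus,
        g=state.g + params.weight * release,
        t_last=state.t_last,
    )
    return new, float(release)


def tm_releases(spike_times: np.ndarray, params: TMParams) -> np.ndarray:
    """Per-spike release fractions from rest, event-driven (vectorised core)."""
    times = np.ascontiguousarray(spike_times, dtype=np.float64)
    return tm_release_train(times, params.tau_d, params.tau_f, params.U)


def conductance_train(spikes: SpikeTrain, params: TMParams, dt: float,
                      duration: float | None = None) -> tuple[np.ndarray, PulseAmplitudes]:
    """Conductance time series and per-pulse amplitudes for a spike train.

    Alternates exact relaxation and jump updates; the g series is evaluated
    analytically between events on the ``dt`` grid (no accumulation error).
    Amplitudes are the conductance jumps weight·release per spike.
    """
    times = np.asarray(spikes.times, dtype=float)
    if duration is None:
        duration = float(times[-1] + 5.0 * params.tau_g) if times.size else 0.0
    n = int(np.floor(duration / dt)) + 1
    grid = np.arange(n) * dt
    g = np.zeros(n)
    releases = tm_releases(times, params)
    amps = params.weight * releases
    # superpose decaying exponentials (g is linear in the jumps)
    for t_sp, a in zip(times, amps):
        k0 = int(np.ceil((t_sp - 1e-12) / dt))
        if k0 < n:
            g[k0:] += a * np.exp(-(grid[k0:] - t_sp) / params.tau_g)
    isi = float(np.median(np.diff(times))) if times.size > 1 else np.nan
    return g, PulseAmplitudes(amps=amps, isi=isi) if times.size else PulseAmplitudes(
        amps=np.empty(0), isi=np.nan)


def tm_steady_state(rate: float, params: TMParams) -> tuple[float, float, float]:
    """Fixed point of the TM map under periodic stimulation at ``rate`` Hz.

    Returns (x_ss, u_ss, release_ss) where x_ss and u_ss are the pre-spike
    values in the periodic steady state and release_ss = u⁺_ss · x_ss.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    delta = 1000.0 / rate
    ef = np.exp(-delta / params.tau_f)
    ed = np.exp(-delta / params.tau_d)
    U = params.U
    u_minus = U * ef / (1.0 - (1.0 - U) * ef)
    u_plus = u_minus + U * (1.0 - u_minus)
    x_minus = (1.0 - ed) / (1.0 - (1.0 - u_plus) * ed)
    return float(x_minus), float(u_minus), float(u_plus * x_minus)


def exp_synapse(spikes: SpikeTrain, weight: float, tau_g: float, dt: float,
                duration: float | None = None) -> np.ndarray:
    """Non-depressing control: fixed jump ``weight`` per spike, decay tau_g."""
    times = np.asarray(spikes.times, dtype=float)
    if duration is None:
        duration = float(times[-1] + 5.0 * tau_g) if times.size else 0.0
    n = int(np.floor(duration / dt)) + 1
    grid = np.arange(n) * dt
    g = np.zeros(n)
    for t_sp in times:
        k0 = int(np.ceil((t_sp - 1e-12) / dt))
        if k0 < n:
            g[k0:] += weight * np.exp(-(grid[k0:] - t_sp) / tau_g)
    return g


def _grid_releases(n_pulses: int, isi: float, tau_d, tau_f, U) -> np.ndarray:
    """Normalized release of pulses 1..n for arrays of (tau_d, tau_f, U).

    Vectorised event-driven recursion over a parameter grid; shapes of
    tau_d, tau_f, U broadcast together.
    """
    ed = np.exp(-isi / tau_d)
    ef = np.exp(-isi / tau_f)
    x = np.ones(np.broadcast(tau_d, tau_f, U).shape)
    u = np.zeros_like(x)
    out = np.empty((n_pulses,) + x.shape)
    for k in range(n_pulses):
        if k > 0:
            x = 1.0 - (1.0 - x) * ed
            u = u * ef
        u = u + U * (1.0 - u)
        out[k] = u * x
        x = x * (1.0 - u)
    return out / out[0]


def fit_tm(amps: PulseAmplitudes,
           tau_d_grid: np.ndarray | None = None,
           tau_f_grid: np.ndarray | None = None,
           u_grid: np.ndarray | None = None) -> tuple[TMParams, float]:
    """Exhaustive grid-search least-squares fit of (τ_d, τ_f, U).

    The model's normalized per-pulse releases at the train's inter-pulse
    interval are matched to the normalized amplitudes; loss is the sum of
    squared differences.  Ties break toward the lexicographically smallest
    (τ_d, τ_f, U).  The synaptic weight is recovered from the raw first
    amplitude (first release from rest equals U).

    Returns (best params, minimum loss).
    """
    if amps.amps.size < 2:
        raise ValueError("need at least 2 pulses to fit")
    if not np.isfinite(amps.isi) or amps.isi <= 0:
        raise ValueError("amplitude train must declare a positive inter-pulse interval")
    if tau_d_grid is None:
        tau_d_grid = np.arange(10.0, 1000.0 + 1e-9, 10.0)
    if tau_f_grid is None:
        tau_f_grid = np.arange(5.0, 500.0 + 1e-9, 5.0)
    if u_grid is None:
        u_grid = np.arange(0.02, 0.98 + 1e-9, 0.02)
    if min(len(tau_d_grid), len(tau_f_grid), len(u_grid)) == 0:
        raise ValueError("parameter grids must be nonempty")
    td, tf, uu = np.meshgrid(tau_d_grid, tau_f_grid, u_grid, indexing="ij")
    model = _grid_releases(len(amps.amps), amps.isi, td, tf, uu)
    target = amps.normalized.reshape((-1,) + (1,) * 3)
    loss = np.sum((model - target) ** 2, axis=0)
    # argmin of the flattened C-ordered array is lexicographically first in
    # (tau_d, tau_f, U), implementing the tie-break
    idx = np.unravel_index(np.argmin(loss), loss.shape)
    best = TMParams(
        tau_d=float(tau_d_grid[idx[0]]),
        tau_f=float(tau_f_grid[idx[1]]),
        U=float(u_grid[idx[2]]),
        weight=float(amps.amps[0] / u_grid[idx[2]]),
    )
    return best, float(loss[idx])
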