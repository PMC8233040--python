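"""Mean-field reduction of the thalamo-retrosplenial circuit.

The stochastic HD ensemble is replaced by a continuum of preferred angles
carrying a depression field x(θ, t):

    ∂x/∂t = (1 − x)/τ_d − U · x · f(θ − θ_A(t)),

where f is the shared tuning curve (in spikes/ms internally) and θ_A the
anticipatory effective trajectory.  The postsynaptic drive is

    D(t) = ∫ U · x(θ, t) · f(θ − θ_A(t)) dθ,

low-pass filtered with the postsynaptic integration time τ_post.
Facilitation is dropped: at the fitted operating point τ_f ≪ τ_d, so
depression dominates the synaptic dynamics.

This reduction is used to check three qualitative claims numerically:
steady drive grows with rotation speed, the low-speed growth is quadratic
(concave-up speed tuning), and anticipation compensates the integration
lag between drive and head speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import analysis
from .trajectory import TWO_PI, Trajectory, angular_velocity, effective_trajectory


@dataclass(frozen=True)
class MeanFieldParams:
    """Continuum-model constants.

    resolution: number of θ grid points over [0, 2π); tuning (f_bg, f_max,
    epsilon) shared by the whole continuum; tau_d ms; U in (0, 1];
    tau_post ms; ati ms.
    """

    resolution: int = 256
    f_bg: float = 3.0
    f_max: float = 40.0
    epsilon: float = 4.5
    tau_d: float = 270.0
    U: float = 0.28
    tau_post: float = 50.0
    ati: float = 0.0

    def __post_init__(self) -> None:
        if self.resolution < 64:
            raise ValueError("resolution must be >= 64")
        if min(self.tau_d, self.tau_post) <= 0 or not (0.0 < self.U <= 1.0):
            raise ValueError("tau_d, tau_post must be positive and U in (0, 1]")
        # aliasing guard: tuning width must span several grid cells
        width = 1.0 / np.sqrt(max(self.epsilon, 1e-12))
        if width < 4.0 * TWO_PI / self.resolution:
            raise ValueError("theta resolution too coarse for this tuning width")


def _tuning(offset: np.ndarray, p: MeanFieldParams) -> np.ndarray:
    """Tuning curve in spikes per ms."""
    return ((p.f_max - p.f_bg) * np.exp(p.epsilon * (np.cos(offset) - 1.0)) + p.f_bg) / 1000.0


def simulate_meanfield(traj: Trajectory, params: MeanFieldParams
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Evolve the depression field along a trajectory.

    Operator splitting per time step: exact relaxation toward 1 with τ_d,
    then exact exponential depletion at the local input rate.  Returns
    (drive series D(t), postsynaptic rate series = low-pass of D).
    """
    theta_grid = np.linspace(0.0, TWO_PI, params.resolution, endpoint=False)
    eff = effective_trajectory(traj, params.ati)
    dt = traj.dt
    ed = np.exp(-dt / params.tau_d)
    x = np.ones(params.resolution)
    dtheta = TWO_PI / params.resolution
    drive = np.empty(len(traj))
    for k in range(len(traj)):
        f_now = _tuning(theta_grid - eff.theta[k], params)
        drive[k] = params.U * np.sum(x * f_now) * dtheta
        x = 1.0 - (1.0 - x) * ed
        x *= np.exp(-params.U * f_now * dt)
    alpha = np.exp(-dt / params.tau_post)
    post = np.empty_like(drive)
    acc = drive[0]
    for k in range(len(drive)):
        acc = alpha * acc + (1.0 - alpha) * drive[k]
        post[k] = acc
    return drive, post


def _steady_drive(omega: float, params: MeanFieldParams, dt: float = 1.0) -> float:
    """Steady-state drive under constant rotation at omega rad/s."""
    # run long enough for the slow field to converge, then average one period
    settle = 8.0 * params.tau_d
    period = TWO_PI / max(abs(omega), 1e-9) * 1000.0
    duration = settle + min(max(period, 500.0), 20_000.0)
    t = np.arange(0.0, duration, dt)
    theta = omega * t / 1000.0
    traj = Trajectory(t=t, theta=theta, dt=dt)
    drive, _ = simulate_meanfield(traj, params)
    tail = t >= settle
    return float(drive[tail].mean())


def speed_scaling(params: MeanFieldParams, omegas) -> tuple[np.ndarray, float]:
    """Steady drive at each rotation speed and the fitted low-speed exponent.

    Fits log(D(ω) − D(0)) against log ω; a quadratic law gives exponent 2.
    """
    omegas = np.asarray(omegas, dtype=float)
    if omegas.size < 2 or np.any(omegas <= 0):
        raise ValueError("need at least two positive rotation speeds")
    d0 = _steady_drive(0.0, params)
    drives = np.array([_steady_drive(w, params) for w in omegas])
    excess = drives - d0
    if np.any(excess <= 0):
        raise ValueError("drive does not exceed the stationary baseline; outside regime")
    slope = np.polyfit(np.log(omegas), np.log(excess), 1)[0]
    return drives, float(slope)


def ati_lag_compensation(params: MeanFieldParams, ati_values, traj: Trajectory,
                         lags=None) -> list[tuple[float, float]]:
    """Optimal lag between mean-field postsynaptic rate and head speed per ATI.

    Returns [(ati, optimal_lag_ms), ...]; anticipation should shrink the
    lag introduced by the postsynaptic integration time.
    """
    if lags is None:
        lags = np.arange(-150.0, 150.0 + 1e-9, 5.0)
    speed = np.abs(angular_velocity(traj).omega)
    out = []
    for a in ati_values:
        p = MeanFieldParams(**{**params.__dict__, "ati": float(a)})
        _, post = simulate_meanfield(traj, p)
        sim = analysis.lagged_correlation(post, speed, lags=lags, dt=traj.dt)
        out.append((float(a), sim.optimal_lag))
    return out
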