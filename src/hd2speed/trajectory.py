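"""Head-direction trajectories and angular velocity.

The head direction θ(t) is kept *unwrapped* internally (a continuous real
number, not reduced modulo 2π) so that interpolation and differentiation
never see an artificial 2π seam.  Wrapping to [0, 2π) is a view.

Units: time in ms, angles in radians, angular velocity in rad/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled head-direction time series.

    Attributes
    ----------
    t : ndarray
        Time grid in ms, strictly increasing with constant step ``dt``.
    theta : ndarray
        Unwrapped head direction in radians.
    dt : float
        Sampling step in ms.
    meta : str
        Provenance tag (``"synthetic"`` or ``"loaded"``).
    """

    t: np.ndarray
    theta: np.ndarray
    dt: float
    meta: str = "synthetic"

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        theta = np.asarray(self.theta, dtype=float)
        if t.ndim != 1 or theta.shape != t.shape:
            raise ValueError("t and theta must be 1-D arrays of equal length")
        if len(t) >= 2:
            steps = np.diff(t)
            if not np.all(steps > 0) or not np.allclose(steps, self.dt, rtol=1e-9, atol=1e-9):
                raise ValueError("t must be strictly increasing with constant step dt")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(theta)):
            raise ValueError("theta must be finite everywhere")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "theta", theta)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Total spanned time in ms."""
        return float(self.t[-1] - self.t[0])

    def wrapped(self) -> np.ndarray:
        """Head direction reduced to [0, 2π); a view for plotting/binning."""
        return np.mod(self.theta, TWO_PI)


@dataclass(frozen=True)
class AngularVelocitySeries:
    """Signed angular velocity (rad/s) and angular head speed on a time grid.

    Positive velocity denotes counterclockwise turning.
    """

    t: np.ndarray
    omega: np.ndarray

    @property
    def speed(self) -> np.ndarray:
        return np.abs(self.omega)

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class OUParams:
    """Ornstein–Uhlenbeck angular-velocity model of a head-tracking session.

    The generator emulates a tracking recording: velocity is an OU process
    sampled at a coarse ``raw_rate`` (default 40 Hz, typical of overhead
    video tracking), integrated to an angle, and linearly interpolated to
    the fine simulation grid — the same treatment a real low-rate tracking
    table receives.

    Attributes
    ----------
    tau_omega : float
        Relaxation time of angular velocity, ms.
    sigma_omega : float
        Stationary standard deviation of angular velocity, rad/s.
    duration : float
        Total time, ms.
    raw_rate : float
        Emulated raw tracking rate, Hz.
    """

    tau_omega: float = 100.0
    sigma_omega: float = 3.0
    duration: float = 120_000.0
    raw_rate: float = 40.0

    def __post_init__(self) -> None:
        if self.tau_omega <= 0 or self.duration <= 0 or self.raw_rate <= 0:
            raise ValueError("tau_omega, duration and raw_rate must be positive")
        if self.sigma_omega < 0:
            raise ValueError("sigma_omega must be nonnegative")


def generate_ou_trajectory(params: OUParams, dt: float = 1.0, seed: int = 0) -> Trajectory:
    """Generate a synthetic head-direction trajectory.

    Angular velocity follows a stationary OU process with relaxation time
    ``tau_omega`` and stationary SD ``sigma_omega``, discretised exactly on
    the raw tracking grid; the angle is its trapezoidal integral, then
    linearly interpolated onto the fine ``dt`` grid.

    Deterministic given ``seed``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if params.duration < 10 * dt:
        raise ValueError("duration must be at least 10 dt")
    rng = np.random.default_rng(seed)
    raw_dt = 1000.0 / params.raw_rate  # ms between raw samples
    n_raw = int(np.floor(params.duration / raw_dt)) + 1
    # exact OU discretisation: w_{k+1} = rho w_k + s * xi
    rho = np.exp(-raw_dt / params.tau_omega)
    s = params.sigma_omega * np.sqrt(1.0 - rho * rho)
    xi = rng.standard_normal(n_raw)
    omega_raw = np.empty(n_raw)
    omega_raw[0] = params.sigma_omega * xi[0]
    for k in range(1, n_raw):
        omega_raw[k] = rho * omega_raw[k - 1] + s * xi[k]
    t_raw = np.arange(n_raw) * raw_dt
    # theta = integral of omega (rad/s) over t (ms): trapezoid, converted to rad
    theta_raw = np.concatenate(
        ([0.0], np.cumsum(0.5 * (omega_raw[1:] + omega_raw[:-1]) * raw_dt / 1000.0))
    )
    t_fine = np.arange(0.0, t_raw[-1] + 0.5 * dt, dt)
    t_fine = t_fine[t_fine <= t_raw[-1] + 1e-9]
    theta_fine = np.interp(t_fine, t_raw, theta_raw)
    return Trajectory(t=t_fine, theta=theta_fine, dt=dt, meta="synthetic")


def load_tracking(table, dt: float, degrees: bool = False) -> Trajectory:
    """Resample a raw (time_s, angle) tracking table onto a uniform grid.

    ``table`` is any sequence of (time_s, angle) records or a 2-column array;
    times in seconds, angles in radians (or degrees with ``degrees=True``).
    The angle is unwrapped before interpolation so the path never crosses the
    0/2π seam in the wrong direction.
    """
    arr = np.asarray(list(table) if not isinstance(table, np.ndarray) else table, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("tracking table must have (time, angle) columns")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 tracking samples")
    t_raw = arr[:, 0] * 1000.0  # s -> ms
    angle = arr[:, 1]
    if degrees:
        angle = np.deg2rad(angle)
    if not np.all(np.diff(t_raw) > 0):
        raise ValueError("tracking times must be strictly increasing")
    theta_raw = np.unwrap(angle)
    t_fine = t_raw[0] + np.arange(int(np.floor((t_raw[-1] - t_raw[0]) / dt)) + 1) * dt
    theta_fine = np.interp(t_fine, t_raw, theta_raw)
    return Trajectory(t=t_fine, theta=theta_fine, dt=dt, meta="loaded")


def angular_velocity(traj: Trajectory) -> AngularVelocitySeries:
    """Angular velocity by centered differences on the unwrapped angle.

    Interior points use (θ(t+dt) − θ(t−dt)) / (2 dt); the two boundary
    samples use one-sided differences so the series stays full length.
    Output in rad/s.
    """
    if len(traj) < 3:
        raise ValueError("need at least 3 samples to differentiate")
    theta = traj.theta
    dt_s = traj.dt / 1000.0
    omega = np.empty_like(theta)
    omega[1:-1] = (theta[2:] - theta[:-2]) / (2.0 * dt_s)
    omega[0] = (theta[1] - theta[0]) / dt_s
    omega[-1] = (theta[-1] - theta[-2]) / dt_s
    return AngularVelocitySeries(t=traj.t, omega=omega)


def effective_trajectory(traj: Trajectory, ati: float) -> Trajectory:
    """Anticipatory-firing transform of a trajectory.

    An HD cell with anticipatory time interval A effectively experiences
    θ_A(t) = θ(t) + A·θ̇(t): at angular velocity ω its preferred angle
    shifts from θ to θ − ωA, i.e. the cell fires A ms early.

    ``ati`` in ms (negative values are accepted but are nonphysiological).
    """
    if ati == 0.0:
        return traj
    omega = angular_velocity(traj).omega
    theta_eff = traj.theta + (ati / 1000.0) * omega
    return Trajectory(t=traj.t, theta=theta_eff, dt=traj.dt, meta=traj.meta)
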