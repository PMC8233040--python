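"""Presynaptic head-direction (HD) cell population.

Each HD cell fires maximally when the head faces its preferred angle (PA).
The tuning curve is the circular Gaussian

    f(θ) = (f_max − f_bg) · exp(ε (cos θ − 1)) + f_bg

with background rate f_bg, peak rate f_max and concentration ε.  Cell
parameters are drawn from shifted/scaled Beta distributions; spike trains
are inhomogeneous Poisson with a 4 ms absolute refractory period.  PA
distributions are either uniform on the circle or random periodic densities
built from Brownian bridges, whose heterogeneity is scored by the circular
1-Wasserstein distance from uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from ._kernels import thin_with_dead_time
from .trajectory import TWO_PI, Trajectory, angular_velocity

DEFAULT_REFRACTORY_MS = 4.0


@dataclass(frozen=True)
class HDCellParams:
    """Tuning parameters of one HD cell.

    f_bg, f_max in Hz; epsilon dimensionless; ati in ms; pa in [0, 2π).
    """

    f_bg: float
    f_max: float
    epsilon: float
    ati: float
    pa: float

    def __post_init__(self) -> None:
        if not (self.f_max >= self.f_bg >= 0.0):
            raise ValueError("require f_max >= f_bg >= 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be nonnegative")
        if not (0.0 <= self.pa < TWO_PI):
            raise ValueError("pa must lie in [0, 2pi)")


@dataclass(frozen=True)
class BetaSpec:
    """Shifted/scaled Beta distribution: support [loc, loc + scale]."""

    a: float
    b: float
    loc: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0 or self.scale <= 0:
            raise ValueError("a, b and scale must be positive")

    @property
    def mean(self) -> float:
        return self.loc + self.scale * self.a / (self.a + self.b)


# Provisional population statistics: consistent with anterodorsal-thalamus HD
# cell ranges (background rates of a few Hz, peak rates of tens of Hz, tuning
# half-widths of several tens of degrees) and a mean anticipatory interval of
# 50 ms.  All config-exposed.
DEFAULT_BETA_FBG = BetaSpec(a=1.5, b=4.0, loc=0.5, scale=9.5)     # mean ~3.1 Hz
DEFAULT_BETA_FMAX = BetaSpec(a=2.0, b=3.0, loc=15.0, scale=60.0)  # mean 39 Hz
DEFAULT_BETA_EPSILON = BetaSpec(a=2.0, b=2.0, loc=1.0, scale=7.0)  # mean 4.5
DEFAULT_BETA_ATI = BetaSpec(a=2.0, b=2.0, loc=0.0, scale=100.0)    # mean 50 ms


@dataclass(frozen=True)
class EnsembleSpec:
    """Population-level description of the presynaptic HD ensemble."""

    n_cells: int = 7500
    beta_fbg: BetaSpec = DEFAULT_BETA_FBG
    beta_fmax: BetaSpec = DEFAULT_BETA_FMAX
    beta_epsilon: BetaSpec = DEFAULT_BETA_EPSILON
    beta_ati: BetaSpec = DEFAULT_BETA_ATI
    fixed_ati: float | None = None
    pa_mode: str = "uniform"        # "uniform" | "bridge"
    bridge_roughness: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.pa_mode not in ("uniform", "bridge"):
            raise ValueError("pa_mode must be 'uniform' or 'bridge'")


@dataclass(frozen=True)
class PADensity:
    """Normalized periodic density of preferred angles on [0, 2π)."""

    grid: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        dens = np.asarray(self.density, dtype=float)
        if np.any(dens < 0):
            raise ValueError("density must be nonnegative")
        integral = _circular_trapz(grid, dens)
        if abs(integral - 1.0) > 1e-9:
            raise ValueError(f"density must integrate to 1 (got {integral:.3g})")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "density", dens)


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times in ms; inter-spike intervals respect the dead time."""

    times: np.ndarray
    refractory: float = DEFAULT_REFRACTORY_MS

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if times.size > 1:
            isi = np.diff(times)
            if np.any(isi <= 0):
                raise ValueError("spike times must be strictly increasing")
            if self.refractory > 0 and np.any(isi < self.refractory - 1e-9):
                raise ValueError("inter-spike interval below refractory period")
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return len(self.times)


def _circular_trapz(grid: np.ndarray, values: np.ndarray) -> float:
    """Trapezoidal integral over the circle, closing the seam grid[-1] -> grid[0]+2π."""
    closed_grid = np.append(grid, grid[0] + TWO_PI)
    closed_vals = np.append(values, values[0])
    return float(np.trapezoid(closed_vals, closed_grid))


def tuning_curve(theta_offset, params: HDCellParams):
    """Circular-Gaussian firing rate at angular offset θ from the PA, in Hz."""
    theta = np.asarray(theta_offset, dtype=float)
    return (params.f_max - params.f_bg) * np.exp(params.epsilon * (np.cos(theta) - 1.0)) + params.f_bg


def sample_beta(spec: BetaSpec, n: int, seed) -> np.ndarray:
    """I.i.d. draws from the shifted/scaled Beta; deterministic given seed."""
    rng = np.random.default_rng(seed)
    return spec.loc + spec.scale * rng.beta(spec.a, spec.b, size=n)


def sample_ensemble(spec: EnsembleSpec) -> list[HDCellParams]:
    """Draw a full HD population.

    Per-parameter Beta draws are independent; (f_bg, f_max) pairs violating
    f_max >= f_bg are redrawn jointly.  PAs follow ``pa_mode``; with
    ``fixed_ati`` set, every cell shares that anticipatory interval.
    """
    ss = np.random.SeedSequence(spec.seed)
    s_fbg, s_fmax, s_eps, s_ati, s_pa = ss.spawn(5)
    n = spec.n_cells
    fbg = sample_beta(spec.beta_fbg, n, s_fbg)
    fmax = sample_beta(spec.beta_fmax, n, s_fmax)
    # joint resample until f_max >= f_bg
    rng_fbg = np.random.default_rng(s_fbg.spawn(1)[0])
    rng_fmax = np.random.default_rng(s_fmax.spawn(1)[0])
    bad = fmax < fbg
    while np.any(bad):
        k = int(bad.sum())
        fbg[bad] = spec.beta_fbg.loc + spec.beta_fbg.scale * rng_fbg.beta(spec.beta_fbg.a, spec.beta_fbg.b, k)
        fmax[bad] = spec.beta_fmax.loc + spec.beta_fmax.scale * rng_fmax.beta(spec.beta_fmax.a, spec.beta_fmax.b, k)
        bad = fmax < fbg
    eps = sample_beta(spec.beta_epsilon, n, s_eps)
    if spec.fixed_ati is not None:
        ati = np.full(n, float(spec.fixed_ati))
    else:
        ati = sample_beta(spec.beta_ati, n, s_ati)
    pas, _ = sample_pa(spec.pa_mode, n, spec.bridge_roughness, s_pa)
    return [
        HDCellParams(f_bg=float(fbg[i]), f_max=float(fmax[i]), epsilon=float(eps[i]),
                     ati=float(ati[i]), pa=float(pas[i]))
        for i in range(n)
    ]


def cell_rate_series(params: HDCellParams, traj: Trajectory,
                     omega: np.ndarray | None = None) -> np.ndarray:
    """Firing-rate series r(t) = f(pa − θ_A(t)) of one HD cell, in Hz.

    θ_A is the cell's anticipatory effective trajectory.  ``omega`` (rad/s,
    same grid) may be supplied to avoid recomputing the shared derivative.
    """
    if params.ati != 0.0:
        if omega is None:
            omega = angular_velocity(traj).omega
        theta_eff = traj.theta + (params.ati / 1000.0) * omega
    else:
        theta_eff = traj.theta
    return tuning_curve(params.pa - theta_eff, params)


def generate_spike_train(rate: np.ndarray, t: np.ndarray,
                         refractory: float = DEFAULT_REFRACTORY_MS,
                         seed=0) -> SpikeTrain:
    """Inhomogeneous Poisson spikes by thinning, with absolute dead time.

    ``rate`` in Hz on the ms grid ``t``.  Candidates are drawn homogeneously
    at the peak rate and accepted with probability r(t)/r_max, except that
    the intensity is held at zero for ``refractory`` ms after each accepted
    spike.  Deterministic given seed.
    """
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rates must be nonnegative")
    if refractory < 0:
        raise ValueError("refractory must be nonnegative")
    rng = np.random.default_rng(seed)
    lam_max = float(rate.max(initial=0.0)) / 1000.0  # spikes per ms
    duration = float(t[-1] - t[0])
    if lam_max <= 0.0 or duration <= 0.0:
        return SpikeTrain(times=np.empty(0), refractory=refractory)
    n_cand = rng.poisson(lam_max * duration)
    cand = np.sort(rng.uniform(t[0], t[-1], size=n_cand))
    cand_rate = np.interp(cand, t, rate) / 1000.0
    uniforms = rng.uniform(size=n_cand)
    accepted = thin_with_dead_time(cand, cand_rate, uniforms, lam_max, float(refractory))
    return SpikeTrain(times=accepted, refractory=refractory)


def _bridge_log_density(n_grid: int, roughness: float, rng) -> np.ndarray:
    """Standard Brownian bridge over [0, 2π), scaled by ``roughness``."""
    increments = rng.standard_normal(n_grid) / np.sqrt(n_grid)
    w = np.concatenate(([0.0], np.cumsum(increments)))  # Wiener path, W(1) ~ N(0,1)
    s = np.linspace(0.0, 1.0, n_grid + 1)
    bridge = w - s * w[-1]
    return roughness * bridge[:-1]  # drop duplicated endpoint; periodic by construction


def sample_pa(mode: str, n: int, roughness: float = 1.0, seed=0,
              n_grid: int = 512) -> tuple[np.ndarray, PADensity]:
    """Draw preferred angles and return the generating density.

    ``uniform``: i.i.d. uniform on [0, 2π) with a flat density.
    ``bridge``: the density is exp(B)/Z for a Brownian bridge B with SD
    parameter ``roughness`` (the bridge is a log-density, guaranteeing
    positivity and 2π-periodicity); samples come from inverse-transform
    sampling of its circular CDF.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if roughness < 0:
        raise ValueError("roughness must be nonnegative")
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, TWO_PI, n_grid, endpoint=False)
    if mode == "uniform" or roughness == 0.0:
        density = np.full(n_grid, 1.0 / TWO_PI)
        samples = rng.uniform(0.0, TWO_PI, size=n)
        return samples, PADensity(grid=grid, density=density)
    if mode != "bridge":
        raise ValueError("mode must be 'uniform' or 'bridge'")
    log_d = _bridge_log_density(n_grid, roughness, rng)
    density = np.exp(log_d)
    density /= _circular_trapz(grid, density)
    pad = PADensity(grid=grid, density=density)
    samples = _inverse_transform_circular(pad, n, rng)
    return samples, pad


def _inverse_transform_circular(pad: PADensity, n: int, rng) -> np.ndarray:
    grid = np.append(pad.grid, TWO_PI)
    dens = np.append(pad.density, pad.density[0])
    cdf = np.concatenate(([0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(grid))))
    cdf /= cdf[-1]
    u = rng.uniform(size=n)
    return np.mod(np.interp(u, cdf, grid), TWO_PI)


def wasserstein_to_uniform(pad: PADensity) -> float:
    """Circular 1-Wasserstein distance between a PA density and uniform.

    With arc-length ground metric, W1 on the circle is
    min_c ∫ |F_p(θ) − F_u(θ) − c| dθ, minimised at the weighted median of
    the CDF difference.  Returns radians; 0 iff uniform.
    """
    grid = np.append(pad.grid, TWO_PI)
    dens = np.append(pad.density, pad.density[0])
    widths = np.diff(grid)
    cdf_p = np.concatenate(([0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * widths)))
    cdf_u = grid / TWO_PI
    delta = cdf_p - cdf_u
    # piecewise evaluation at segment midpoints, weighted by segment length
    mid = 0.5 * (delta[1:] + delta[:-1])
    order = np.argsort(mid)
    w = widths[order]
    cum = np.cumsum(w)
    c_star = mid[order][np.searchsorted(cum, 0.5 * cum[-1])]
    return float(np.sum(np.abs(mid - c_star) * widths))
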