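"""In-silico experiments: speed coding, anticipation sweep, population tradeoff.

Each experiment wires the stages together: synthetic (or loaded) trajectory
→ HD ensemble spiking → depressing / non-depressing synaptic drive →
rate-based LR readout → coding analysis.  All randomness flows from one
master seed through spawned per-cell streams, so results are reproducible
bit-for-bit and independent of iteration order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import analysis
from ._kernels import exp_filter
from .ensemble import (DEFAULT_REFRACTORY_MS, EnsembleSpec, HDCellParams,
                       PADensity, cell_rate_series, generate_spike_train,
                       sample_ensemble, sample_pa, tuning_curve,
                       wasserstein_to_uniform)
from .readout import RateReadoutParams, rate_readout
from .synapse import TMParams, tm_releases
from .trajectory import OUParams, Trajectory, angular_velocity, generate_ou_trajectory


@dataclass(frozen=True)
class ExperimentConfig:
    """Fully serializable description of one simulation run."""

    ou: OUParams = OUParams()
    ensemble: EnsembleSpec = EnsembleSpec(n_cells=1000)
    tm: TMParams = TMParams()
    readout: RateReadoutParams = RateReadoutParams()
    dt: float = 1.0
    lags: tuple = tuple(analysis.DEFAULT_LAGS)
    mi_bins: int = analysis.DEFAULT_MI_BINS
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), default=list)


@dataclass
class SpeedCodingResult:
    """Speed-coding experiment bundle: both synapse modes on the same inputs."""

    t: np.ndarray
    speed: np.ndarray
    rate_depressing: np.ndarray
    rate_nondepressing: np.ndarray
    corr_depressing: analysis.LagSimilarity
    corr_nondepressing: analysis.LagSimilarity
    mi_depressing: analysis.LagSimilarity
    mi_nondepressing: analysis.LagSimilarity
    speed_tuning: analysis.SpeedTuning
    ahv_tuning: analysis.SpeedTuning
    presyn_active_corr: np.ndarray
    presyn_active_excluded: int
    config: dict


def _ensemble_drive(traj: Trajectory, cells: list[HDCellParams], tm: TMParams,
                    mode: str, seed) -> np.ndarray:
    """Summed synaptic conductance of the whole ensemble, per-synapse normalized.

    Each cell's spikes are drawn by thinning its rate series; per-spike
    conductance jumps (TM release × weight, or fixed weight in the
    non-depressing mode) are binned onto the trajectory grid and passed
    through the shared exponential conductance decay.  Division by the cell
    count makes the drive scale independent of ensemble size.
    """
    omega = angular_velocity(traj).omega
    n = len(traj)
    impulses = np.zeros(n)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(len(cells))
    for cell, stream in zip(cells, streams):
        r = cell_rate_series(cell, traj, omega=omega)
        spikes = generate_spike_train(r, traj.t, refractory=DEFAULT_REFRACTORY_MS,
                                      seed=stream)
        if len(spikes) == 0:
            continue
        if mode == "depressing":
            jumps = tm.weight * tm_releases(spikes.times, tm)
        elif mode == "non_depressing":
            # matched control: same decay and a jump equal to the depressing
            # synapse's first-pulse response from rest (weight * U)
            jumps = np.full(len(spikes), tm.weight * tm.U)
        else:
            raise ValueError("mode must be 'depressing' or 'non_depressing'")
        idx = np.clip(np.round((spikes.times - traj.t[0]) / traj.dt).astype(int), 0, n - 1)
        np.add.at(impulses, idx, jumps)
    g = exp_filter(impulses, float(np.exp(-traj.dt / tm.tau_g)))
    return g / len(cells)


def simulate_lr_rate(traj: Trajectory, cells: list[HDCellParams], tm: TMParams,
                     readout: RateReadoutParams, mode: str, seed) -> np.ndarray:
    """LR firing-rate series for one synapse mode (Hz)."""
    g = _ensemble_drive(traj, cells, tm, mode, seed)
    return rate_readout(g, readout, traj.dt)


def run_speed_coding(config: ExperimentConfig,
                     traj: Trajectory | None = None,
                     cells: list[HDCellParams] | None = None) -> SpeedCodingResult:
    """Speed-coding experiment: depressing vs non-depressing synapses.

    Both modes see the identical trajectory and HD population.  Outputs the
    lagged correlation and MI curves against angular head speed, the speed
    and signed-velocity tuning of the depressing-mode rate, and the
    active-window presynaptic correlation distribution.
    """
    ss = np.random.SeedSequence(config.seed)
    s_traj, s_dep, s_nondep = ss.spawn(3)
    if traj is None:
        traj = generate_ou_trajectory(config.ou, dt=config.dt, seed=s_traj)
    if cells is None:
        cells = sample_ensemble(config.ensemble)
    av = angular_velocity(traj)
    speed = av.speed
    lags = np.asarray(config.lags)

    rate_dep = simulate_lr_rate(traj, cells, config.tm, config.readout, "depressing", s_dep)
    rate_non = simulate_lr_rate(traj, cells, config.tm, config.readout, "non_depressing", s_nondep)

    corr_dep = analysis.lagged_correlation(rate_dep, speed, lags=lags, dt=traj.dt)
    corr_non = analysis.lagged_correlation(rate_non, speed, lags=lags, dt=traj.dt)
    mi_dep = analysis.lagged_mutual_information(rate_dep, speed, lags=lags, dt=traj.dt,
                                                bins=config.mi_bins)
    mi_non = analysis.lagged_mutual_information(rate_non, speed, lags=lags, dt=traj.dt,
                                                bins=config.mi_bins)

    # tuning curves of the depressing-mode rate against speed at the optimal lag
    best_lag, _ = analysis.optimal_lag(corr_dep)
    k = int(round(best_lag / traj.dt))
    r_al, s_al = analysis._lagged_pairs(rate_dep, speed, k)
    _, v_al = analysis._lagged_pairs(rate_dep, av.omega, k)
    tuning = analysis.speed_tuning_curve(r_al, s_al, n_bins=12)
    vmax = np.quantile(np.abs(v_al), 0.99)
    ahv_edges = np.linspace(-vmax, vmax, 13)
    ahv = analysis.speed_tuning_curve(r_al, v_al, bin_edges=ahv_edges)

    # presynaptic control: HD rates carry no explicit speed signal
    omega = av.omega
    sub = cells[:: max(1, len(cells) // 200)]  # a representative subset
    presyn_rates = (cell_rate_series(c, traj, omega=omega) for c in sub)
    pre_corr, pre_excl = analysis.active_window_correlation(presyn_rates, speed)

    return SpeedCodingResult(
        t=traj.t, speed=speed,
        rate_depressing=rate_dep, rate_nondepressing=rate_non,
        corr_depressing=corr_dep, corr_nondepressing=corr_non,
        mi_depressing=mi_dep, mi_nondepressing=mi_non,
        speed_tuning=tuning, ahv_tuning=ahv,
        presyn_active_corr=pre_corr, presyn_active_excluded=pre_excl,
        config=config.to_dict(),
    )


def run_ati_sweep(config: ExperimentConfig, ati_values,
                  lags=None) -> pd.DataFrame:
    """Fixed-ATI anticipation sweep, depressing synapses only.

    The trajectory and the per-cell tuning draws are shared across arms
    (paired design); only the anticipatory interval differs, so residual
    variability across arms comes from spike sampling alone.  A wider lag
    grid than the ±70 ms default is used so the zero-anticipation optimum
    is not clipped at the grid edge.

    Returns a DataFrame with columns ati_ms, optimal_lag_ms, max_corr,
    max_mi.
    """
    ati_values = list(ati_values)
    if not ati_values or any(a < 0 for a in ati_values):
        raise ValueError("ati_values must be nonempty and nonnegative")
    if lags is None:
        lags = np.arange(-150.0, 150.0 + 1e-9, 5.0)
    ss = np.random.SeedSequence(config.seed)
    s_traj, _ = ss.spawn(2)
    traj = generate_ou_trajectory(config.ou, dt=config.dt, seed=s_traj)
    speed = angular_velocity(traj).speed
    base_cells = sample_ensemble(config.ensemble)
    # arm streams keyed by the ATI value itself: permuting the sweep order
    # permutes the outputs exactly (no hidden state)
    arm_seeds = [np.random.SeedSequence((config.seed, 0x5EED, int(round(a * 1000))))
                 for a in ati_values]
    rows = []
    for a, s_arm in zip(ati_values, arm_seeds):
        cells = [dataclasses.replace(c, ati=float(a)) for c in base_cells]
        rate = simulate_lr_rate(traj, cells, config.tm, config.readout, "depressing", s_arm)
        corr = analysis.lagged_correlation(rate, speed, lags=lags, dt=traj.dt)
        mi = analysis.lagged_mutual_information(rate, speed, lags=lags, dt=traj.dt,
                                                bins=config.mi_bins)
        lag, cmax = analysis.optimal_lag(corr)
        rows.append({"ati_ms": float(a), "optimal_lag_ms": lag,
                     "max_corr": cmax, "max_mi": analysis.optimal_lag(mi)[1]})
    return pd.DataFrame(rows)


def run_population_tradeoff(config: ExperimentConfig, n_lr: int = 200,
                            roughness_range: tuple[float, float] = (0.0, 2.5)
                            ) -> pd.DataFrame:
    """Direction/speed coding tradeoff across a population of LR cells.

    Each simulated LR cell draws its own nonuniform preferred-angle density
    (Brownian-bridge log-density with roughness uniform over
    ``roughness_range``), receives input from an HD pool sampled from it,
    and is scored for heterogeneity (circular Wasserstein distance from
    uniform, ``wd``), speed coding (max lagged correlation and MI with
    head speed) and direction coding (circular–linear correlation and MI
    with head direction).

    Returns one row per LR cell.
    """
    if n_lr < 2:
        raise ValueError("n_lr must be >= 2")
    ss = np.random.SeedSequence(config.seed)
    s_traj, s_pop = ss.spawn(2)
    traj = generate_ou_trajectory(config.ou, dt=config.dt, seed=s_traj)
    av = angular_velocity(traj)
    speed = av.speed
    theta_wrapped = traj.wrapped()
    lags = np.asarray(config.lags)
    lr_seeds = s_pop.spawn(n_lr)
    rows = []
    for i, s_lr in enumerate(lr_seeds):
        s_rough, s_pa, s_cells, s_spk = s_lr.spawn(4)
        rough = np.random.default_rng(s_rough).uniform(*roughness_range)
        pas, pad = sample_pa("bridge", config.ensemble.n_cells, roughness=rough, seed=s_pa)
        wd = wasserstein_to_uniform(pad)
        cells = _ensemble_with_pas(config.ensemble, pas, s_cells)
        rate = simulate_lr_rate(traj, cells, config.tm, config.readout, "depressing", s_spk)
        corr_speed = analysis.lagged_correlation(rate, speed, lags=lags, dt=traj.dt)
        mi_speed = analysis.lagged_mutual_information(rate, speed, lags=lags, dt=traj.dt,
                                                      bins=config.mi_bins)
        mi_dir, corr_dir = analysis.direction_information(rate, theta_wrapped,
                                                          bins=config.mi_bins)
        lag, cmax = analysis.optimal_lag(corr_speed)
        rows.append({
            "lr_cell": i, "roughness": float(rough), "wd": wd,
            "corr_speed": cmax, "mi_speed": analysis.optimal_lag(mi_speed)[1],
            "corr_dir": corr_dir, "mi_dir": mi_dir, "optimal_lag_ms": lag,
        })
    return pd.DataFrame(rows)


def _ensemble_with_pas(spec: EnsembleSpec, pas: np.ndarray, seed) -> list[HDCellParams]:
    """Sample tuning parameters for a pool whose PAs are already drawn."""
    tmp = dataclasses.replace(spec, n_cells=len(pas), pa_mode="uniform")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    base = sample_ensemble(dataclasses.replace(tmp, seed=int(ss.generate_state(1)[0] % (2**31))))
    return [dataclasses.replace(c, pa=float(p)) for c, p in zip(base, pas)]
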