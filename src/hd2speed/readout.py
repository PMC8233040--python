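"""Postsynaptic low-rheobase (LR) cell readouts.

The reference readout is rate-based: the summed synaptic conductance of the
ensemble is low-pass filtered with a membrane time constant and mapped
affinely to a firing rate.  The coding quantities downstream (Pearson
correlation, mutual information) are invariant to the affine map, so the
gain and baseline only set the plotted scale.

A conductance-based spiking point neuron (fast sodium, delayed-rectifier
potassium, and a slow Kv1.1-like potassium conductance, driven through the
conductance form g·(E_syn − V)) is provided as a secondary readout for
cross-checking the sign and ordering of the coding results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from ._kernels import hh_step_loop
from .ensemble import SpikeTrain


@dataclass(frozen=True)
class RateReadoutParams:
    """First-order rate readout: low-pass with tau_m, then affine map.

    tau_m ms; gain Hz per unit (per-synapse-normalized) conductance;
    baseline Hz.  Defaults put desk-scale depressing-input output in the
    tens-of-Hz range.
    """

    tau_m: float = 35.0
    gain: float = 4500.0
    baseline: float = 0.0
    rectify: bool = True

    def __post_init__(self) -> None:
        if self.tau_m <= 0 or self.gain <= 0 or self.baseline < 0:
            raise ValueError("tau_m and gain must be positive, baseline nonnegative")


@dataclass(frozen=True)
class PointNeuronParams:
    """Single-compartment spiking LR model (units: mS/cm², mV, µF/cm², ms)."""

    capacitance: float = 1.0
    g_leak: float = 0.1
    e_leak: float = -65.0
    g_na: float = 35.0
    e_na: float = 55.0
    g_kdr: float = 9.0
    e_k: float = -90.0
    g_kslow: float = 0.3
    tau_kslow: float = 100.0
    e_syn: float = 0.0
    spike_threshold: float = -10.0
    reset_level: float = -40.0

    def __post_init__(self) -> None:
        if min(self.g_leak, self.g_na, self.g_kdr, self.g_kslow) < 0:
            raise ValueError("conductances must be nonnegative")
        if self.capacitance <= 0 or self.tau_kslow <= 0:
            raise ValueError("capacitance and tau_kslow must be positive")


def sum_conductances(series) -> np.ndarray:
    """Elementwise sum of per-synapse conductance series on a shared grid."""
    series = [np.asarray(s, dtype=float) for s in series]
    if not series:
        raise ValueError("need at least one conductance series")
    n = len(series[0])
    if any(len(s) != n for s in series):
        raise ValueError("conductance series must share the time grid")
    return np.sum(series, axis=0)


def rate_readout(total_g: np.ndarray, params: RateReadoutParams, dt: float) -> np.ndarray:
    """Rate-based LR response: low-pass filter + affine map, in Hz."""
    total_g = np.asarray(total_g, dtype=float)
    alpha = np.exp(-dt / params.tau_m)
    # exact discrete first-order low-pass with unit DC gain
    filtered = signal.lfilter([1.0 - alpha], [1.0, -alpha], total_g)
    rate = params.baseline + params.gain * filtered
    if params.rectify:
        rate = np.maximum(rate, 0.0)
    return rate


def hh_point_neuron(total_g: np.ndarray, params: PointNeuronParams, dt: float,
                    internal_dt: float = 0.025) -> tuple[SpikeTrain, np.ndarray]:
    """Integrate the spiking point neuron driven by a conductance series.

    ``total_g`` (mS/cm²) on a ``dt`` ms grid is resampled to the internal
    integration step (≤ 0.025 ms).  Spikes are upward threshold crossings
    with hysteresis.  Returns (SpikeTrain, membrane potential on the
    internal grid).
    """
    total_g = np.asarray(total_g, dtype=float)
    if internal_dt > 0.025:
        internal_dt = 0.025
    t_coarse = np.arange(len(total_g)) * dt
    n_fine = int(np.floor(t_coarse[-1] / internal_dt)) + 1 if len(total_g) > 1 else 1
    t_fine = np.arange(n_fine) * internal_dt
    g_fine = np.interp(t_fine, t_coarse, total_g)
    spikes, v = hh_step_loop(
        g_fine, internal_dt, params.capacitance, params.g_leak, params.e_leak,
        params.g_na, params.e_na, params.g_kdr, params.e_k,
        params.g_kslow, params.tau_kslow, params.e_syn,
        params.e_leak, params.spike_threshold, params.reset_level,
    )
    if not np.all(np.isfinite(v)):
        raise FloatingPointError("membrane integration diverged; reduce input or dt")
    return SpikeTrain(times=spikes, refractory=0.0), v


def estimate_firing_rate(spikes: SpikeTrain, kernel_sd: float, dt: float,
                         duration: float) -> np.ndarray:
    """Gaussian-kernel firing-rate estimate on a ``dt`` grid, in Hz.

    Edge-corrected so that the integral of the estimate over the window
    equals the spike count.
    """
    if kernel_sd <= 0:
        raise ValueError("kernel_sd must be positive")
    n = int(np.floor(duration / dt)) + 1
    counts = np.zeros(n)
    if len(spikes):
        idx = np.clip(np.round(spikes.times / dt).astype(int), 0, n - 1)
        np.add.at(counts, idx, 1.0)
    sigma = kernel_sd / dt
    smooth = gaussian_filter1d(counts, sigma, mode="constant")
    # renormalise by the in-window kernel mass to conserve spike count at edges
    mass = gaussian_filter1d(np.ones(n), sigma, mode="constant")
    smooth = smooth / np.maximum(mass, 1e-12)
    return smooth / (dt / 1000.0)
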