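"""Speed- and direction-coding metrics.

Similarity between two series x_t, y_t is always evaluated as the lagged
measure M(x_t, y_{t−l}) over a grid of lags l: with x the postsynaptic rate
and y the angular head speed, a positive optimal lag means the rate tracks
speed l ms in the past.  Two measures are used: Pearson correlation and
plug-in mutual information on 40-bin equal-width discretizations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_LAGS = np.arange(-70.0, 70.0 + 1e-9, 5.0)
DEFAULT_MI_BINS = 40
MIN_OVERLAP = 100


@dataclass(frozen=True)
class LagSimilarity:
    """Lag-indexed similarity curve with its maximising lag.

    ``values`` may contain NaN where the measure was undefined (e.g. a
    zero-variance overlap); these lags are ignored by the optimum.
    """

    lags: np.ndarray
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if lags.shape != values.shape or lags.ndim != 1:
            raise ValueError("lags and values must be matching 1-D arrays")
        if np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be sorted increasing")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", values)

    @property
    def optimal_lag(self) -> float:
        return optimal_lag(self)[0]

    @property
    def max_value(self) -> float:
        return optimal_lag(self)[1]


@dataclass(frozen=True)
class SpeedTuning:
    """Binned speed (or signed-velocity) tuning of a firing rate."""

    bin_edges: np.ndarray
    mean_rate: np.ndarray
    sd_rate: np.ndarray
    counts: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[1:] + self.bin_edges[:-1])


def _lagged_pairs(x: np.ndarray, y: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Overlapping segments of (x_t, y_{t−k}) for an integer sample lag k."""
    if k > 0:
        return x[k:], y[:-k]
    if k < 0:
        return x[:k], y[-k:]
    return x, y


def _check_lag_grid(lags, dt: float) -> np.ndarray:
    lags = np.asarray(lags, dtype=float)
    ks = lags / dt
    if not np.allclose(ks, np.round(ks), atol=1e-6):
        raise ValueError("every lag must be an integer multiple of dt")
    return np.round(ks).astype(int)


def lagged_correlation(x, y, lags=DEFAULT_LAGS, dt: float = 1.0) -> LagSimilarity:
    """Lagged Pearson correlation corr(x_t, y_{t−l}) per lag l (ms).

    Lags whose overlap is shorter than ``MIN_OVERLAP`` samples or has zero
    variance yield NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must share the time grid")
    ks = _check_lag_grid(lags, dt)
    values = np.empty(len(ks))
    for i, k in enumerate(ks):
        xs, ys = _lagged_pairs(x, y, k)
        if len(xs) < MIN_OVERLAP or xs.std() == 0.0 or ys.std() == 0.0:
            values[i] = np.nan
            continue
        values[i] = np.corrcoef(xs, ys)[0, 1]
    return LagSimilarity(lags=np.asarray(lags, dtype=float), values=values, kind="correlation")


def mutual_information(x: np.ndarray, y: np.ndarray, bins: int = DEFAULT_MI_BINS) -> float:
    """Plug-in mutual information (bits) of equal-width binned series."""
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / (px @ py)[mask])))


def lagged_mutual_information(x, y, lags=DEFAULT_LAGS, dt: float = 1.0,
                              bins: int = DEFAULT_MI_BINS) -> LagSimilarity:
    """Lagged plug-in MI (bits) between binned x_t and y_{t−l} per lag l."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must share the time grid")
    ks = _check_lag_grid(lags, dt)
    values = np.empty(len(ks))
    for i, k in enumerate(ks):
        xs, ys = _lagged_pairs(x, y, k)
        if len(xs) < MIN_OVERLAP:
            values[i] = np.nan
            continue
        values[i] = mutual_information(xs, ys, bins=bins)
    return LagSimilarity(lags=np.asarray(lags, dtype=float), values=values, kind="mutual_information")


def optimal_lag(sim: LagSimilarity) -> tuple[float, float]:
    """Maximising lag of a similarity curve.

    Ties break toward the smallest |lag|, then the negative lag.
    Raises if every value is undefined.
    """
    finite = np.isfinite(sim.values)
    if not np.any(finite):
        raise ValueError("no valid lag: all similarity values undefined")
    vmax = np.nanmax(sim.values)
    cand = np.flatnonzero(finite & (sim.values >= vmax - 1e-12))
    order = sorted(cand, key=lambda i: (abs(sim.lags[i]), sim.lags[i]))
    i = order[0]
    return float(sim.lags[i]), float(sim.values[i])


def speed_tuning_curve(rate, speed, bin_edges=None, n_bins: int = 12) -> SpeedTuning:
    """Per-bin mean and SD of firing rate, binned by speed (or signed AHV).

    Pass symmetric ``bin_edges`` spanning negative and positive velocities
    for the signed-velocity variant.  Empty bins carry NaN means/SDs.
    """
    rate = np.asarray(rate, dtype=float)
    speed = np.asarray(speed, dtype=float)
    if rate.shape != speed.shape:
        raise ValueError("series must share the time grid")
    if bin_edges is None:
        bin_edges = np.linspace(speed.min(), speed.max(), n_bins + 1)
    bin_edges = np.asarray(bin_edges, dtype=float)
    idx = np.clip(np.digitize(speed, bin_edges) - 1, 0, len(bin_edges) - 2)
    nb = len(bin_edges) - 1
    mean = np.full(nb, np.nan)
    sd = np.full(nb, np.nan)
    counts = np.zeros(nb, dtype=int)
    for b in range(nb):
        sel = idx == b
        counts[b] = int(sel.sum())
        if counts[b]:
            mean[b] = rate[sel].mean()
            sd[b] = rate[sel].std()
    return SpeedTuning(bin_edges=bin_edges, mean_rate=mean, sd_rate=sd, counts=counts)


def active_window_correlation(cell_rates, speed, threshold: float = 10.0):
    """Per-cell correlation of HD-cell rate with speed in active windows.

    For each presynaptic cell, Pearson correlation between its rate series
    and the head speed restricted to samples where the rate exceeds
    ``threshold`` Hz.  Cells that are never active, have too few active
    samples, or have zero variance while active are excluded.

    Returns (values array, n_excluded).
    """
    speed = np.asarray(speed, dtype=float)
    values = []
    excluded = 0
    for r in cell_rates:
        r = np.asarray(r, dtype=float)
        mask = r > threshold
        if mask.sum() < MIN_OVERLAP:
            excluded += 1
            continue
        ra, sa = r[mask], speed[mask]
        if ra.std() == 0.0 or sa.std() == 0.0:
            excluded += 1
            continue
        values.append(np.corrcoef(ra, sa)[0, 1])
    return np.asarray(values), excluded


def circular_linear_correlation(x: np.ndarray, theta: np.ndarray) -> float:
    """Circular–linear correlation of a linear variable with an angle.

    The multiple correlation of x on (cos θ, sin θ) — equivalently the
    correlation of x with its best-fitting cosine of direction.  In [0, 1].
    """
    x = np.asarray(x, dtype=float)
    rxc = np.corrcoef(x, np.cos(theta))[0, 1]
    rxs = np.corrcoef(x, np.sin(theta))[0, 1]
    rcs = np.corrcoef(np.cos(theta), np.sin(theta))[0, 1]
    num = rxc ** 2 + rxs ** 2 - 2.0 * rxc * rxs * rcs
    return float(np.sqrt(max(num / (1.0 - rcs ** 2), 0.0)))


def direction_information(rate, theta, bins: int = DEFAULT_MI_BINS) -> tuple[float, float]:
    """Direction-coding scores of a firing rate.

    Returns (plug-in MI in bits between the 40-bin rate and 40-bin wrapped
    direction, circular–linear correlation coefficient).
    """
    rate = np.asarray(rate, dtype=float)
    theta = np.mod(np.asarray(theta, dtype=float), 2.0 * np.pi)
    mi = mutual_information(rate, theta, bins=bins)
    return mi, circular_linear_correlation(rate, theta)


def mi_shuffle_bias(x: np.ndarray, y: np.ndarray, bins: int, n_shuffles: int,
                    seed=0) -> float:
    """Mean plug-in MI of independently shuffled pairs (the estimator bias)."""
    rng = np.random.default_rng(seed)
    vals = [mutual_information(x, rng.permutation(y), bins=bins) for _ in range(n_shuffles)]
    return float(np.mean(vals))


def permutation_pvalue_spearman(a, b, n_perm: int = 2000, seed=0) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided permutation p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    rho = stats.spearmanr(a, b).statistic
    rng = np.random.default_rng(seed)
    null = np.array([stats.spearmanr(a, rng.permutation(b)).statistic for _ in range(n_perm)])
    p = (np.sum(np.abs(null) >= abs(rho)) + 1.0) / (n_perm + 1.0)
    return float(rho), float(p)
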