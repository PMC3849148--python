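"""Spike detection, Gaussian-filtered trains, the reliability measure R, ISI stats.

Reliability across an N-trial ensemble is the mean pairwise normalized inner
product of Gaussian-filtered spike trains,

    R = 2 / (N (N-1)) * sum_{i<j} <s_i, s_j> / (|s_i| |s_j|),

with each train convolved with a unit-amplitude Gaussian of width sigma_c
(default 20 ms).  R lies in [0, 1]: 1 for identical non-empty trains, near 0
for unrelated timing.  A pair in which either filtered train is identically
zero (a silent trial) contributes 0 — a silent trial is treated as maximally
unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpikeDetectionConfig",
    "ReliabilityConfig",
    "detect_spikes",
    "values_at_times",
    "filter_train",
    "reliability_R",
    "isi_stats",
]


@dataclass(frozen=True)
class SpikeDetectionConfig:
    """Threshold-crossing spike detection: working threshold vth (mV), debounce (ms)."""

    vth: float = -20.0
    min_separation: float = 30.0

    def __post_init__(self) -> None:
        if self.min_separation <= 0:
            raise ValueError("min_separation must be positive")


@dataclass(frozen=True)
class ReliabilityConfig:
    """Gaussian filter width sigma_c (ms) and trial count for the R measure."""

    sigma_c: float = 20.0
    N: int = 45

    def __post_init__(self) -> None:
        if self.sigma_c <= 0:
            raise ValueError("sigma_c must be positive")
        if self.N < 2:
            raise ValueError("need at least 2 trials")


def detect_spikes(t: np.ndarray, v: np.ndarray,
                  config: SpikeDetectionConfig = SpikeDetectionConfig()) -> np.ndarray:
    """Times of upward crossings of vth, sub-step interpolated, debounced.

    Crossings closer than ``min_separation`` to the previously accepted spike
    are discarded.  An empty array is a valid result.
    """
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    below = v[:-1] < config.vth
    above = v[1:] >= config.vth
    idx = np.nonzero(below & above)[0]
    if idx.size == 0:
        return np.empty(0)
    frac = (config.vth - v[idx]) / (v[idx + 1] - v[idx])
    times = t[idx] + frac * (t[idx + 1] - t[idx])
    kept = [times[0]]
    for tc in times[1:]:
        if tc - kept[-1] >= config.min_separation:
            kept.append(tc)
    return np.asarray(kept)


def values_at_times(t: np.ndarray, x: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Linear interpolation of a trajectory variable at given times (e.g. w at vth)."""
    return np.interp(np.asarray(times, float), t, x)


def filter_train(train: np.ndarray, sigma_c: float, t_grid: np.ndarray) -> np.ndarray:
    """Sum of unit-amplitude Gaussians exp(-(t - ti)^2 / (2 sigma_c^2)) on t_grid.

    Gaussians are truncated at +-6 sigma_c (relative error < 1e-7).
    """
    t_grid = np.asarray(t_grid, float)
    out = np.zeros_like(t_grid)
    if len(train) == 0:
        return out
    dt = t_grid[1] - t_grid[0] if t_grid.size > 1 else 1.0
    half = 6.0 * sigma_c
    for ti in np.asarray(train, float):
        lo = int(np.searchsorted(t_grid, ti - half, side="left"))
        hi = int(np.searchsorted(t_grid, ti + half, side="right"))
        if hi <= lo:
            continue
        seg = t_grid[lo:hi]
        out[lo:hi] += np.exp(-((seg - ti) ** 2) / (2.0 * sigma_c**2))
    return out


def reliability_R(raster, config: ReliabilityConfig = ReliabilityConfig(),
                  t_grid: np.ndarray | None = None) -> float:
    """Reliability R of an ensemble: mean pairwise cosine of filtered trains.

    ``raster`` is a RasterSet or a plain list of spike-time arrays.  The trains
    are sampled on ``t_grid`` (default: the raster's analysis window on its
    simulation grid).  R is invariant to a common time shift and to trial
    order, and is bounded in [0, 1] by Cauchy-Schwarz.
    """
    if hasattr(raster, "spike_times"):
        trains = raster.spike_times
        if t_grid is None:
            t0, t1 = raster.analysis_window()
            t_grid = np.arange(t0, t1 + raster.dt / 2, raster.dt)
    else:
        trains = list(raster)
        if t_grid is None:
            raise ValueError("t_grid required when passing bare spike trains")
    n = len(trains)
    if n < 2:
        raise ValueError("need at least 2 trials")
    S = np.empty((n, t_grid.size))
    for i, tr in enumerate(trains):
        S[i] = filter_train(tr, config.sigma_c, t_grid)
    norms = np.linalg.norm(S, axis=1)
    G = S @ S.T
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if norms[i] > 0.0 and norms[j] > 0.0:
                total += G[i, j] / (norms[i] * norms[j])
    return float(2.0 * total / (n * (n - 1)))


def isi_stats(train: np.ndarray) -> dict:
    """Interspike intervals with mean and coefficient of variation.

    Fewer than two spikes yield an empty ISI list and NaN summaries.
    """
    train = np.sort(np.asarray(train, float))
    if train.size < 2:
        return {"isis": np.empty(0), "mean": float("nan"), "cv": float("nan")}
    isis = np.diff(train)
    mean = float(np.mean(isis))
    cv = float(np.std(isis, ddof=1) / mean) if isis.size > 1 and mean > 0 else 0.0
    return {"isis": isis, "mean": mean, "cv": cv}
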