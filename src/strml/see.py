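"""Spike-evoking epoch (SEE) extraction, classification, STAs and action statistics.

An SEE is the stretch of the frozen input signal immediately preceding (and
causing) a spike.  Events are anchored at the threshold-crossing times of a
reference trial; the spikes the same epoch evokes on the other trials are
matched by nearest time within a window.  An SEE is *reliable* when every trial
spikes and the spread (max - min of the matched times) is below a cutoff
(default 20 ms); *unreliable* when every trial spikes but the spread is at or
above the cutoff; *unclassifiable* when some trial has no matching spike (a
miss is not evidence about timing spread, so such events enter neither pool).

The *action* of an SEE over a lookback L is the mean current delivered in the
last L ms before the anchor: the area under the signal excerpt divided by L.
The spike-triggered average (STA) is the per-bin mean of the aligned excerpts.
Reliable SEEs can be subdivided into equal-count action tertiles, each with its
own sub-STA and firing-time-SD distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .signals import ExtrinsicSignal
from .integrate import RasterSet

__all__ = [
    "SEEClassConfig",
    "SEERecord",
    "STAProfile",
    "ActionProfile",
    "extract_sees",
    "compute_sta",
    "action",
    "action_profile",
    "w_at_threshold",
    "tertile_analysis",
    "hypothesis_tests",
]

LABELS = ("reliable", "unreliable", "unclassifiable")


@dataclass(frozen=True)
class SEEClassConfig:
    """Classification rule: trials required, spread cutoff (ms), match window (ms).

    ``match_window`` is the full width of the interval around an anchor within
    which a trial's spike is associated to the event; the default 150 ms covers
    the largest unreliable spreads observed (~115 ms).  ``lookback`` is the
    excerpt length stored per SEE.
    """

    n_trials: int = 30
    spread_cutoff: float = 20.0
    match_window: float = 150.0
    lookback: float = 100.0

    def __post_init__(self) -> None:
        if self.spread_cutoff <= 0:
            raise ValueError("spread_cutoff must be positive")
        if self.n_trials < 2:
            raise ValueError("n_trials must be at least 2")


@dataclass
class SEERecord:
    """One spike-evoking epoch with its cross-trial statistics and label."""

    anchor: float                       # reference threshold-crossing time, ms
    excerpt: np.ndarray                 # signal over [anchor - lookback, anchor]
    matched_times: np.ndarray           # per-trial spike time (NaN = miss)
    spread: float                       # max - min of matched times, ms
    label: str                          # reliable | unreliable | unclassifiable
    firing_sd: float                    # SD of matched times across trials, ms
    w_values: np.ndarray                # per-trial w at the vth crossing (NaN = miss)
    dt: float
    note: str = ""

    @property
    def mean_w(self) -> float:
        vals = self.w_values[np.isfinite(self.w_values)]
        return float(np.mean(vals)) if vals.size else float("nan")


@dataclass
class STAProfile:
    """Spike-triggered average: mean input waveform over the pre-anchor window."""

    window: float                       # ms
    bin_width: float                    # ms
    waveform: np.ndarray                # uA/cm^2, oldest lag first
    n_sees: int

    @property
    def lags(self) -> np.ndarray:
        """Bin-center lags in ms, negative (past) up to 0 (the anchor)."""
        nb = self.waveform.size
        return -self.window + (np.arange(nb) + 0.5) * self.bin_width


@dataclass
class ActionProfile:
    """action(L) for a grid of lookback lengths L (ms)."""

    L_grid: np.ndarray
    values: np.ndarray                  # uA/cm^2


def extract_sees(signal: ExtrinsicSignal, raster: RasterSet,
                 config: SEEClassConfig = SEEClassConfig()) -> list[SEERecord]:
    """Extract and classify SEEs from an ensemble run on a frozen signal.

    Candidate anchors are the reference trial's (trial 0) spike times.  For
    each anchor, the nearest spike of every trial within +-match_window/2 is
    associated to the event.  Events whose matched sets overlap with the
    previous event are not silently dropped: they are kept with label
    'unclassifiable' and a merge note.  Anchors too early for a full lookback
    excerpt are likewise unclassifiable.
    """
    if raster.n_trials < config.n_trials:
        raise ValueError(f"raster has {raster.n_trials} trials, need {config.n_trials}")
    trains = raster.spike_times[: config.n_trials]
    w_lists = raster.w_at_spikes[: config.n_trials]
    dt = signal.dt
    half = config.match_window / 2.0
    n_ex = int(round(config.lookback / dt))
    records: list[SEERecord] = []
    prev_matched: set | None = None
    for anchor in np.asarray(trains[0], float):
        matched = np.full(config.n_trials, np.nan)
        w_vals = np.full(config.n_trials, np.nan)
        keyset = set()
        for i in range(config.n_trials):
            tr = np.asarray(trains[i], float)
            if tr.size == 0:
                continue
            k = int(np.argmin(np.abs(tr - anchor)))
            if abs(tr[k] - anchor) <= half:
                matched[i] = tr[k]
                w_vals[i] = np.asarray(w_lists[i], float)[k]
                keyset.add((i, k))
        ia = int(round(anchor / dt))
        note = ""
        if prev_matched is not None and keyset & prev_matched:
            label, note = "unclassifiable", "overlaps previous event"
        elif ia < n_ex or ia > signal.n:
            label, note = "unclassifiable", "insufficient signal history"
        elif np.isnan(matched).any():
            label = "unclassifiable"
        else:
            spread_ok = (matched.max() - matched.min()) < config.spread_cutoff
            label = "reliable" if spread_ok else "unreliable"
        prev_matched = keyset
        good = matched[np.isfinite(matched)]
        spread = float(good.max() - good.min()) if good.size else float("nan")
        firing_sd = float(np.std(good, ddof=1)) if good.size > 1 else float("nan")
        excerpt = signal.values[max(ia - n_ex, 0): ia].copy()
        records.append(SEERecord(anchor=float(anchor), excerpt=excerpt,
                                 matched_times=matched, spread=spread, label=label,
                                 firing_sd=firing_sd, w_values=w_vals, dt=dt,
                                 note=note))
    return records


def compute_sta(sees: Sequence[SEERecord], window: float = 100.0,
                bin_width: float | None = None) -> STAProfile:
    """Per-bin average of the aligned signal excerpts preceding the anchors.

    All excerpts must share the grid; the window cannot exceed the stored
    lookback.  With the default bin width (one sample) the Heaviside-difference
    windowing of the STA definition reduces to per-sample averaging.
    """
    sees = [s for s in sees]
    if not sees:
        raise ValueError("need at least one SEE")
    dt = sees[0].dt
    if any(not np.isclose(s.dt, dt) for s in sees):
        raise ValueError("all excerpts must share the same grid")
    n_w = int(round(window / dt))
    if any(s.excerpt.size < n_w for s in sees):
        raise ValueError("window exceeds stored excerpt length")
    stack = np.stack([s.excerpt[-n_w:] for s in sees])
    wave = stack.mean(axis=0)
    if bin_width is None:
        bin_width = dt
    nb = int(round(window / bin_width))
    per = n_w // nb
    if per > 1:
        wave = wave[: nb * per].reshape(nb, per).mean(axis=1)
    return STAProfile(window=window, bin_width=window / wave.size,
                      waveform=wave, n_sees=len(sees))


def action(see: SEERecord | np.ndarray, L: float, dt: float | None = None) -> float:
    """Mean current over the last L ms before the anchor: trapezoidal area / L.

    For a constant excerpt the result equals that constant for every L.
    """
    if L <= 0:
        raise ValueError("lookback L must be positive")
    if isinstance(see, SEERecord):
        x, dt = see.excerpt, see.dt
    else:
        x = np.asarray(see, float)
        if dt is None:
            raise ValueError("dt required for bare arrays")
    m = int(round(L / dt))
    if m > x.size:
        raise ValueError(f"L={L} ms exceeds excerpt length {x.size * dt:.1f} ms")
    m = min(m, x.size - 1)  # L equal to the full excerpt: drop one interval
    seg = x[-(m + 1):]
    return float(np.trapezoid(seg, dx=dt) / (m * dt))


def action_profile(see: SEERecord, L_grid: Sequence[float] | None = None) -> ActionProfile:
    """action(L) over a lookback grid (default 5, 10, ..., up to the excerpt length)."""
    if L_grid is None:
        L_max = see.excerpt.size * see.dt
        L_grid = np.arange(5.0, L_max + 1e-9, 5.0)
    L_grid = np.asarray(L_grid, float)
    vals = np.array([action(see, L) for L in L_grid])
    return ActionProfile(L_grid=L_grid, values=vals)


def w_at_threshold(trajectory, spike_time: float, vth: float = -20.0) -> float:
    """w interpolated at the instant a detected upward vth crossing occurs.

    The crossing fraction is recomputed from the bracketing samples so the
    interpolation is exact for piecewise-linear trajectories.
    """
    t, v, w = trajectory.t, trajectory.v, trajectory.w
    i = int(np.searchsorted(t, spike_time)) - 1
    i = min(max(i, 0), t.size - 2)
    if v[i + 1] == v[i]:
        return float(w[i])
    frac = (vth - v[i]) / (v[i + 1] - v[i])
    frac = min(max(frac, 0.0), 1.0)
    return float(w[i] + frac * (w[i + 1] - w[i]))


def tertile_analysis(reliable_sees: Sequence[SEERecord], L: float = 20.0,
                     sta_window: float = 100.0) -> dict:
    """Split reliable SEEs into equal-count action tertiles at lookback L.

    SEEs are ordered by action(L) (ties broken by anchor time), split into
    low/medium/high thirds whose counts differ by at most one, and summarized:
    per-tertile sub-STA, firing-time SDs, and the low-vs-high comparisons
    (two-sample t on mean firing-time SD, F on action variance).
    """
    sees = list(reliable_sees)
    if len(sees) < 9:
        raise ValueError(f"need at least 9 reliable SEEs, got {len(sees)}")
    acts = np.array([action(s, L) for s in sees])
    order = sorted(range(len(sees)), key=lambda i: (acts[i], sees[i].anchor))
    thirds = np.array_split(np.asarray(order), 3)
    names = ("low", "medium", "high")
    out: dict = {"L": L, "assignments": {}, "sub_stas": {}, "firing_sds": {},
                 "actions": {}}
    for name, idx in zip(names, thirds):
        members = [sees[i] for i in idx]
        out["assignments"][name] = [sees[i].anchor for i in idx]
        out["sub_stas"][name] = compute_sta(members, window=sta_window)
        out["firing_sds"][name] = np.array([m.firing_sd for m in members])
        out["actions"][name] = acts[idx]
    lo, hi = out["firing_sds"]["low"], out["firing_sds"]["high"]
    out["tests"] = {
        "firing_sd_low_vs_high": hypothesis_tests(lo, hi, "two-sample-t"),
    }
    return out


def hypothesis_tests(groupA, groupB, kind: str) -> dict:
    """Two-sided tests: paired t, two-sample t (pooled variance), or F on variances.

    Identical paired groups give statistic 0 and p = 1; otherwise degenerate
    zero-variance inputs raise.
    """
    a = np.asarray(groupA, float)
    b = np.asarray(groupB, float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 observations per group")
    if kind == "paired-t":
        if a.size != b.size:
            raise ValueError("paired test requires equal lengths")
        d = a - b
        if np.all(d == 0.0):
            return {"statistic": 0.0, "p": 1.0}
        if np.var(d, ddof=1) == 0.0:
            raise ValueError("degenerate input: zero-variance differences")
        res = stats.ttest_rel(a, b)
    elif kind == "two-sample-t":
        if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
            if np.mean(a) == np.mean(b):
                return {"statistic": 0.0, "p": 1.0}
            raise ValueError("degenerate input: both groups have zero variance")
        res = stats.ttest_ind(a, b, equal_var=True)
    elif kind == "F-variance":
        s1, s2 = np.var(a, ddof=1), np.var(b, ddof=1)
        if s2 == 0.0:
            raise ValueError("degenerate input: zero variance in second group")
        F = s1 / s2
        d1, d2 = a.size - 1, b.size - 1
        p = 2.0 * min(stats.f.sf(F, d1, d2), stats.f.cdf(F, d1, d2))
        return {"statistic": float(F), "p": float(min(p, 1.0))}
    else:
        raise ValueError("kind must be 'paired-t', 'two-sample-t' or 'F-variance'")
    return {"statistic": float(res.statistic), "p": float(res.pvalue)}
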