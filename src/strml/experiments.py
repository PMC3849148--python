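"""Config-driven experiment designs: reliability sweeps, rasters, STA insertion, spectra.

Each experiment builds its frozen signals, runs trial ensembles with
independent per-trial intrinsic streams, and returns plain tables
(pandas DataFrames) plus the underlying objects.  Every stochastic run records
its seeds, so re-running from the same config reproduces all numbers exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .model import MLParameters, preset
from .signals import (ExtrinsicSignal, EpochLibrary, build_signal, splice_signal,
                      insert_sta_copies, power_spectrum)
from .integrate import run_ensemble, RasterSet
from .metrics import reliability_R, ReliabilityConfig
from .see import extract_sees, compute_sta, SEEClassConfig, SEERecord

__all__ = [
    "ExperimentConfig",
    "experiment_reliability_sweep",
    "experiment_raster",
    "experiment_sta_insertion",
    "experiment_spectral",
    "build_epoch_library",
    "run_see_pipeline",
]


@dataclass
class ExperimentConfig:
    """Settings shared by the experiment drivers.

    Durations are model time in ms and include the burn-in that is discarded
    before analysis.  ``seeds`` are master seeds: each entry drives one
    independent replicate (frozen signal + intrinsic streams).
    """

    variant: str = "TypeII"
    delta1: float | None = None          # None: preset default
    delta2: float | None = None
    tau: float | None = None
    n_trials: int = 20
    duration: float = 20500.0
    burn_in: float = 500.0
    seeds: Sequence[int] = (1, 2, 3)
    sd_grid: Sequence[float] = (0.5, 1.0, 2.0, 4.0)
    tau_grid: Sequence[float] = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
    sigma_c: float = 20.0
    mode: str = "increment"

    def __post_init__(self) -> None:
        if len(self.seeds) == 0 or len(self.sd_grid) == 0 or len(self.tau_grid) == 0:
            raise ValueError("seed and sweep grids must be non-empty")

    def params(self) -> MLParameters:
        p = preset(self.variant)
        kw = {}
        if self.delta1 is not None:
            kw["delta1"] = self.delta1
        if self.delta2 is not None:
            kw["delta2"] = self.delta2
        if self.tau is not None:
            kw["tau"] = self.tau
        return p.with_(**kw) if kw else p


def _one_R(params: MLParameters, signal: ExtrinsicSignal, cfg: ExperimentConfig,
           master_seed: int) -> float:
    raster = run_ensemble(params, signal, cfg.n_trials, master_seed=master_seed,
                          burn_in=cfg.burn_in, mode=cfg.mode)
    return reliability_R(raster, ReliabilityConfig(sigma_c=cfg.sigma_c, N=cfg.n_trials))


def experiment_reliability_sweep(config: ExperimentConfig, sweep: str = "sd",
                                 construction: str = "filtered") -> pd.DataFrame:
    """R across a grid of stimulus SD values or correlation times.

    sweep='sd': the extrinsic SD (= delta2 under the normalized convention) is
    varied at the preset's tau.  sweep='tau': the correlation time is varied at
    the preset's delta2, the SD held fixed by the unit-variance normalization.
    Each grid point is replicated over the config's master seeds with a fresh
    frozen signal per seed; the result has one row per (x, seed) plus
    mean/SD aggregates.
    """
    base = config.params()
    rows = []
    grid = config.sd_grid if sweep == "sd" else config.tau_grid
    if sweep not in ("sd", "tau"):
        raise ValueError("sweep must be 'sd' or 'tau'")
    for x in grid:
        p = base.with_(delta2=float(x)) if sweep == "sd" else base.with_(tau=float(x))
        for seed in config.seeds:
            try:
                sig = build_signal(p, config.duration, seed=int(seed),
                                   construction=construction)
                R = _one_R(p, sig, config, master_seed=int(seed) + 7919)
            except Exception as err:  # noqa: BLE001 - annotate grid point
                raise RuntimeError(f"sweep failed at {sweep}={x}, seed={seed}") from err
            rows.append({sweep: float(x), "seed": int(seed), "R": R,
                         "empirical_sd": sig.empirical_sd()})
    df = pd.DataFrame(rows)
    agg = df.groupby(sweep)["R"].agg(["mean", "std"]).reset_index()
    return df.merge(agg, on=sweep, suffixes=("", "_agg")).rename(
        columns={"mean": "R_mean", "std": "R_sd"})


def experiment_raster(config: ExperimentConfig, seed: int | None = None) -> dict:
    """Constant vs. frozen-fluctuating input at matched mean: rasters and R values."""
    p = config.params()
    seed = int(config.seeds[0]) if seed is None else seed
    sig_const = build_signal(p.with_(delta2=0.0), config.duration, seed=seed)
    sig_fluct = build_signal(p, config.duration, seed=seed)
    out = {}
    for name, sig in (("constant", sig_const), ("frozen", sig_fluct)):
        raster = run_ensemble(p, sig, config.n_trials, master_seed=seed + 31,
                              burn_in=config.burn_in, mode=config.mode)
        out[name] = {"raster": raster, "signal": sig,
                     "R": reliability_R(raster, ReliabilityConfig(config.sigma_c,
                                                                  config.n_trials))}
    return out


def run_see_pipeline(config: ExperimentConfig, see_config: SEEClassConfig | None = None,
                     seed: int | None = None) -> dict:
    """One frozen-signal ensemble plus SEE extraction/classification.

    Returns the signal, raster, all SEE records, and the reliable/unreliable
    pools (events whose full lookback window is free of earlier reference
    spikes are additionally provided as the 'isolated' pools, minimizing
    spike-interaction effects).
    """
    p = config.params()
    seed = int(config.seeds[0]) if seed is None else seed
    if see_config is None:
        see_config = SEEClassConfig(n_trials=config.n_trials)
    sig = build_signal(p, config.duration, seed=seed)
    raster = run_ensemble(p, sig, max(config.n_trials, see_config.n_trials),
                          master_seed=seed + 97, burn_in=config.burn_in,
                          mode=config.mode)
    sees = extract_sees(sig, raster, see_config)
    anchors = np.array([s.anchor for s in sees])
    pre_gap = np.diff(anchors, prepend=-np.inf)
    isolated = [s for s, g in zip(sees, pre_gap) if g >= see_config.lookback]
    out = {
        "params": p, "signal": sig, "raster": raster, "sees": sees,
        "reliable": [s for s in sees if s.label == "reliable"],
        "unreliable": [s for s in sees if s.label == "unreliable"],
        "isolated_reliable": [s for s in isolated if s.label == "reliable"],
        "isolated_unreliable": [s for s in isolated if s.label == "unreliable"],
    }
    return out


def _verified_nonspiking(params: MLParameters, epoch: np.ndarray, dt: float,
                         seed: int = 0, n_verify: int = 5, pre: float = 400.0,
                         post: float = 100.0, mode: str = "increment") -> bool:
    """True if the epoch, presented alone on a constant-Ic baseline, stays quiet.

    A few trials with fresh intrinsic noise are run on [Ic ... epoch ... Ic];
    the epoch passes when fewer than half of the trials spike between its onset
    and 50 ms past its end (purely intrinsic-noise spikes far from the epoch do
    not count against it).
    """
    values = np.concatenate([np.full(int(round(pre / dt)), params.Ic), epoch,
                             np.full(int(round(post / dt)), params.Ic)])
    sig = ExtrinsicSignal(dt=dt, values=values, meta={"Ic": params.Ic,
                                                      "construction": "verify"})
    raster = run_ensemble(params, sig, max(n_verify, 2), master_seed=seed,
                          burn_in=0.0, mode=mode)
    lo, hi = pre, pre + epoch.size * dt + 50.0
    n_spiking = sum(1 for tr in raster.spike_times
                    if np.any((np.asarray(tr) >= lo) & (np.asarray(tr) <= hi)))
    return n_spiking < max(n_verify, 2) / 2


def build_epoch_library(params: MLParameters, n_segments: int = 5,
                        segment_duration: float = 10000.0, seed: int = 0,
                        n_trials: int = 10, max_sees: int = 112,
                        max_nonspiking: int = 45, epoch_pre: float = 100.0,
                        epoch_post: float = 10.0, nonspiking_len: float = 50.0,
                        burn_in: float = 500.0, mode: str = "increment") -> EpochLibrary:
    """Harvest labelled epochs from fresh stimulation segments.

    Several independent filtered-noise segments are presented to a small trial
    ensemble; spike-evoking epochs are cut around anchors on which the ensemble
    agrees (every trial spikes within the match window).  Non-spiking epochs
    are random windows of the same segments verified *in isolation*: the window
    is embedded in a constant-Ic baseline and presented to a few trials, and it
    is kept only when fewer than half of them spike near it — so its label is
    an empirical fact about the epoch itself, not about its original context.
    Every epoch records its source seed and window; a mean-diverse subset of
    the quiet pool is retained so gap filling can steer spliced-signal means.
    """
    sees: list[np.ndarray] = []
    quiet_cand: list[tuple[np.ndarray, dict]] = []
    prov = {"sees": [], "nonspiking": []}
    cfg = SEEClassConfig(n_trials=n_trials)
    dt = None
    for k in range(n_segments):
        seg_seed = seed + 1000 * (k + 1)
        sig = build_signal(params, segment_duration + burn_in, seed=seg_seed)
        dt = sig.dt
        raster = run_ensemble(params, sig, n_trials, master_seed=seg_seed + 13,
                              burn_in=burn_in, mode=mode)
        records = extract_sees(sig, raster, cfg)
        n_pre = int(round(epoch_pre / dt))
        n_post = int(round(epoch_post / dt))
        for rec in records:
            if rec.label == "unclassifiable" or len(sees) >= max_sees:
                continue
            ia = int(round(rec.anchor / dt))
            if ia - n_pre < 0 or ia + n_post > sig.n:
                continue
            sees.append(sig.values[ia - n_pre: ia + n_post].copy())
            prov["sees"].append({"seed": seg_seed, "window_ms": [float((ia - n_pre) * dt),
                                                                 float((ia + n_post) * dt)]})
        # non-spiking: random windows kept only if verified quiet in isolation
        n_len = int(round(nonspiking_len / dt))
        rng = np.random.default_rng(seg_seed + 7)
        n_draw = max(6 * max_nonspiking // max(n_segments, 1), 12)
        offsets = rng.integers(int(burn_in / dt), sig.n - n_len, size=n_draw)
        for i0 in offsets:
            epoch = sig.values[i0: i0 + n_len].copy()
            if _verified_nonspiking(params, epoch, dt, seed=seg_seed + int(i0), mode=mode):
                quiet_cand.append((epoch, {"seed": seg_seed,
                                           "window_ms": [float(i0 * dt),
                                                         float((i0 + n_len) * dt)]}))
    if not sees or not quiet_cand:
        raise RuntimeError(
            f"epoch harvest failed: {len(sees)} spike-evoking and {len(quiet_cand)} "
            "non-spiking epochs found; lengthen the segments or relax the windows")
    # keep a mean-diverse subset: evenly spaced quantiles of the mean-sorted
    # candidates, so the gap filler retains corrective epochs on both sides
    k = min(max_nonspiking, len(quiet_cand))
    quiet_cand.sort(key=lambda eq: float(np.mean(eq[0])))
    idx = np.unique(np.linspace(0, len(quiet_cand) - 1, k).round().astype(int))
    chosen = [quiet_cand[i] for i in idx]
    quiet = [e for e, _ in chosen]
    prov["nonspiking"] = [p for _, p in chosen]
    return EpochLibrary(dt=dt, Ic=params.Ic, sees=sees, nonspiking=quiet, provenance=prov)


def experiment_sta_insertion(config: ExperimentConfig, library: EpochLibrary | None = None,
                             sees: Sequence[SEERecord] | None = None,
                             n_copies: int = 20, gaps: Sequence[float] = (60.0, 90.0, 120.0),
                             sta_window: float = 100.0, seed: int | None = None) -> dict:
    """Insert STA copies into non-spiking background and measure the response.

    The STA is computed from a pool of SEEs (built in-run when not supplied),
    copies are spliced between verified non-spiking gaps, and the ensemble
    response is summarized by R and by the fraction of insertions followed by
    an ensemble-consensus spike (majority of trials) within ~one STA window
    after the copy's onset.
    """
    p = config.params()
    seed = int(config.seeds[0]) if seed is None else seed
    if sees is None:
        pipe = run_see_pipeline(config, seed=seed)
        sees = pipe["reliable"] + pipe["unreliable"]
    if library is None:
        library = build_epoch_library(p, n_segments=2, seed=seed + 5,
                                      n_trials=min(config.n_trials, 10))
    sta = compute_sta(sees, window=sta_window)
    sig = insert_sta_copies(sta.waveform, library, n_copies, gaps, seed=seed)
    raster = run_ensemble(p, sig, config.n_trials, master_seed=seed + 59,
                          burn_in=0.0, mode=config.mode)
    R = reliability_R(raster, ReliabilityConfig(config.sigma_c, config.n_trials),
                      t_grid=np.arange(0.0, sig.duration, sig.dt))
    onsets = np.asarray(sig.meta["onsets"], float)
    window = sta_window + 20.0
    hits = 0
    for onset in onsets:
        n_spk = sum(1 for tr in raster.spike_times
                    if np.any((np.asarray(tr) > onset) & (np.asarray(tr) <= onset + window)))
        hits += n_spk >= raster.n_trials / 2
    return {"sta": sta, "signal": sig, "raster": raster, "R": R,
            "onset_success": hits / len(onsets), "n_onsets": len(onsets)}


def experiment_spectral(config: ExperimentConfig, library: EpochLibrary,
                        schedules: Sequence[Sequence[tuple[int, float]]] | None = None,
                        seed: int | None = None) -> pd.DataFrame:
    """Reliability across spliced signals with distinct spectral content.

    Default schedules: SEEs at strictly regular spacing (a sharp spectral peak
    at 1/spacing), at a different regular spacing, and at irregular spacings
    (broadband).  Returns one row per signal with its dominant spectral peak
    (searched below 0.02 kHz) and R.
    """
    p = config.params()
    seed = int(config.seeds[0]) if seed is None else seed
    n_sees = len(library.sees)
    if schedules is None:
        # regular spacings put a spectral line at 1/period; the irregular one is broadband
        epoch_len = library.sees[0].size * library.dt
        rng = np.random.default_rng(seed)
        periods = (156.0, epoch_len + 15.0)
        reg = [[(i % n_sees, max(T - epoch_len, 15.0)) for i in range(18)]
               for T in periods]
        irregular = [(i % n_sees, float(g)) for i, g in
                     enumerate(rng.uniform(30.0, 160.0, size=16))]
        schedules = reg + [irregular]
    rows = []
    for k, sched in enumerate(schedules):
        sig = splice_signal(library, sched, seed=seed + k)
        f, pw = power_spectrum(sig)
        sel = (f > 0.0005) & (f < 0.02)
        f_peak = float(f[sel][np.argmax(pw[sel])])
        raster = run_ensemble(p, sig, config.n_trials, master_seed=seed + 211 + k,
                              burn_in=0.0, mode=config.mode)
        R = reliability_R(raster, ReliabilityConfig(config.sigma_c, config.n_trials),
                          t_grid=np.arange(0.0, sig.duration, sig.dt))
        rows.append({"signal": k, "peak_freq_kHz": f_peak, "R": R,
                     "duration_ms": sig.duration,
                     "mean_spikes": float(raster.spike_counts().mean())})
    return pd.DataFrame(rows)
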