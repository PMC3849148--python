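"""Synthetic input-current construction: frozen extrinsic noise, splicing, spectra.

The extrinsic stimulus is ``Iext(t) = Ic + delta2 * eta2(t)`` where ``eta2`` is
unit-intensity Gaussian white noise convolved with the alpha kernel
``alpha(t) = (t / tau^2) exp(-t / tau)`` (unit area, correlation time ~tau).
One realization is *frozen*: the identical sample path is presented on every
trial, while intrinsic noise differs per trial.  For unit white-noise intensity
the stationary SD of ``eta2`` is ``1 / (2 sqrt(tau))``, so the stimulus SD is
``delta2 / (2 sqrt(tau))``.

Besides plain filtered/white constructions, signals can be spliced together
from a library of stored epochs (spike-evoking and non-spiking excerpts) with
controlled spacing, which is how test signals with prescribed spectral content
are produced, and a spike-triggered-average waveform can be inserted repeatedly
into non-spiking background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve, periodogram

from .model import MLParameters

__all__ = [
    "ExtrinsicSignal",
    "EpochLibrary",
    "alpha_kernel",
    "filtered_noise",
    "filtered_noise_sd",
    "build_signal",
    "splice_signal",
    "insert_sta_copies",
    "power_spectrum",
]

DT_DEFAULT = 1.0 / 30.0  # ms; shared with the integrator step


def filtered_noise_sd(delta2: float, tau: float) -> float:
    """Stationary SD of the filtered extrinsic noise delta2*eta2, = delta2/(2*sqrt(tau))."""
    return delta2 / (2.0 * np.sqrt(tau))


@dataclass
class ExtrinsicSignal:
    """A frozen extrinsic current sampled on a fixed dt grid.

    ``values`` holds Iext(t) = Ic + fluctuation in uA/cm^2; ``meta`` carries
    provenance (tau, delta2, Ic, seed, construction, and construction-specific
    extras such as SEE onset times for spliced signals).
    """

    dt: float
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("signal values must be one-dimensional")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Total duration in ms (n samples cover n*dt of integration steps)."""
        return self.n * self.dt

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n) * self.dt

    @property
    def Ic(self) -> float:
        return float(self.meta.get("Ic", np.mean(self.values)))

    def fluctuation(self) -> np.ndarray:
        """Stochastic part Iext - Ic."""
        return self.values - self.Ic

    def empirical_sd(self) -> float:
        return float(np.std(self.fluctuation()))

    # -- plain-text persistence (CSV + JSON sidecar) ---------------------------

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        arr = np.column_stack([self.t, self.values])
        np.savetxt(path, arr, delimiter=",", header="t_ms,Iext", comments="",
                   fmt="%.17g")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"dt": self.dt, **_json_safe(self.meta)}, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExtrinsicSignal":
        path = Path(path)
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        dt = meta.pop("dt")
        return cls(dt=dt, values=arr[:, 1], meta=meta)


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def alpha_kernel(tau: float, dt: float = DT_DEFAULT, cutoff: float | None = None) -> np.ndarray:
    """Samples of the unit-area alpha kernel (t/tau^2) exp(-t/tau) on the dt grid.

    The kernel is truncated at ``cutoff`` (default 15*tau; must be >= 10*tau so
    the omitted tail is negligible).  ``dt >= tau`` is rejected: the kernel
    would be under-resolved.
    """
    if dt >= tau:
        raise ValueError(f"dt={dt} must resolve the kernel: require dt < tau={tau}")
    if cutoff is None:
        cutoff = 15.0 * tau
    if cutoff < 10.0 * tau:
        raise ValueError("cutoff must be at least 10*tau")
    t = np.arange(0.0, cutoff + dt / 2, dt)
    return (t / tau**2) * np.exp(-t / tau)


def filtered_noise(tau: float, dt: float, duration: float,
                   seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Unit-intensity alpha-filtered Gaussian noise eta2, stationary from sample 0.

    Discretizes eta2(t) = integral alpha(T) dW(t-T): white increments of
    variance dt convolved with the sampled kernel.  A full kernel length of
    extra increments is generated up front so no burn-in remains in the output.
    Long-run SD approaches 1/(2*sqrt(tau)).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    kernel = alpha_kernel(tau, dt)
    n = int(round(duration / dt))
    dW = rng.normal(0.0, np.sqrt(dt), size=n + kernel.size - 1)
    eta2 = fftconvolve(dW, kernel, mode="valid")
    assert eta2.size == n
    return eta2


def build_signal(params: MLParameters, duration: float, seed: int | None = None,
                 construction: str = "filtered", target_sd: float | None = None,
                 dt: float = DT_DEFAULT, normalize: bool = True) -> ExtrinsicSignal:
    """Construct a frozen extrinsic signal Iext = Ic + fluctuation.

    construction='filtered': fluctuation = delta2 * eta2 with eta2 the
    alpha-filtered noise (correlation time params.tau) normalized to unit
    variance, so the stimulus SD equals delta2 irrespective of tau — the
    convention under which signal strength and correlation time are varied
    independently.  ``normalize=False`` keeps the raw unit-intensity
    convolution (SD delta2/(2*sqrt(tau))).  'white': iid Gaussian samples with
    per-sample SD ``target_sd`` (default delta2, for SD-matched comparisons).
    delta2 = 0 yields a constant signal at Ic.
    """
    n = int(round(duration / dt))
    if construction == "filtered":
        if params.delta2 == 0.0:
            fluct = np.zeros(n)
        else:
            eta2 = filtered_noise(params.tau, dt, duration, seed)
            if normalize:
                kernel = alpha_kernel(params.tau, dt)
                eta2 = eta2 / np.sqrt(np.sum(kernel**2) * dt)
            fluct = params.delta2 * eta2
    elif construction == "white":
        sd = target_sd if target_sd is not None else params.delta2
        rng = np.random.default_rng(seed)
        fluct = sd * rng.normal(size=n)
    else:
        raise ValueError("construction must be 'filtered' or 'white'")
    values = params.Ic + fluct
    meta = {
        "tau": params.tau, "delta2": params.delta2, "Ic": params.Ic,
        "seed": seed, "construction": construction,
        "empirical_sd": float(np.std(fluct)), "normalized": normalize,
    }
    if construction == "white":
        meta["target_sd"] = target_sd
    return ExtrinsicSignal(dt=dt, values=values, meta=meta)


@dataclass
class EpochLibrary:
    """Stored signal excerpts with verified spike-triggering labels.

    ``sees`` are spike-evoking epochs, ``nonspiking`` are excerpts verified not
    to trigger a spike under reference conditions; ``provenance`` records the
    source-signal seed and excerpt window for every epoch.
    """

    dt: float
    Ic: float
    sees: list = field(default_factory=list)
    nonspiking: list = field(default_factory=list)
    provenance: dict = field(default_factory=lambda: {"sees": [], "nonspiking": []})

    def __post_init__(self) -> None:
        self.sees = [np.asarray(e, dtype=float) for e in self.sees]
        self.nonspiking = [np.asarray(e, dtype=float) for e in self.nonspiking]

    # -- directory persistence: CSV per epoch + JSON index ---------------------

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        index = {"dt": self.dt, "Ic": self.Ic,
                 "sees": [], "nonspiking": [], "provenance": _json_safe(self.provenance)}
        for kind, epochs in (("sees", self.sees), ("nonspiking", self.nonspiking)):
            for i, e in enumerate(epochs):
                name = f"{kind}_{i:04d}.csv"
                np.savetxt(d / name, e, fmt="%.17g")
                index[kind].append(name)
        (d / "index.json").write_text(json.dumps(index, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "EpochLibrary":
        d = Path(directory)
        index = json.loads((d / "index.json").read_text())
        return cls(
            dt=index["dt"], Ic=index["Ic"],
            sees=[np.loadtxt(d / n) for n in index["sees"]],
            nonspiking=[np.loadtxt(d / n) for n in index["nonspiking"]],
            provenance=index.get("provenance", {}),
        )


def _fill_gap(n_gap: int, pool: list[np.ndarray], order: list[int], used: list,
              running_sum: float, running_n: int, Ic: float,
              future_sum: float = 0.0, future_n: int = 0, future_gap: int = 0):
    """Fill a gap of n_gap samples from non-spiking epochs, steering the mean to Ic.

    Greedy draws: each draw takes the epoch (or crop) whose mean best corrects
    the running deviation of the *whole* signal from Ic, spreading the required
    correction over every gap sample still to come (``future_gap``), with the
    already-scheduled fixed epochs (``future_sum`` over ``future_n`` samples)
    accounted for.  Only the immediately preceding epoch is excluded from a
    draw: quiet material is biased below Ic (sustained above-mean stretches
    tend to trigger spikes), so the corrective high-mean epochs must remain
    reusable or long gap runs could not hold the signal mean.  Epoch interiors
    are never rescaled; pieces are only cropped, at the offset whose slice mean
    best matches the correction target.  Returns (samples, running_sum,
    running_n); raises on an empty pool.
    """
    if not order:
        raise ValueError("mean preservation infeasible: non-spiking epoch pool is empty")
    recent = 1
    parts = []
    filled = 0
    while filled < n_gap:
        avail = [i for i in order if i not in used[-recent:]] or list(order)
        rem_gap = (n_gap - filled) + future_gap
        total_n = running_n + rem_gap + future_n
        target = (Ic * total_n - running_sum - future_sum) / rem_gap
        need = n_gap - filled
        best, best_piece, best_err = None, None, np.inf
        for i in avail:
            ep = pool[i]
            if need < ep.size:
                # best crop: the offset whose slice mean is closest to the target
                csum = np.concatenate([[0.0], np.cumsum(ep)])
                means = (csum[need:] - csum[:-need]) / need
                off = int(np.argmin(np.abs(means - target)))
                piece, err = ep[off: off + need], abs(means[off] - target)
            else:
                piece, err = ep, abs(float(np.mean(ep)) - target)
            if err < best_err:
                best, best_piece, best_err = i, piece, err
        used.append(best)
        piece = best_piece
        parts.append(piece)
        filled += piece.size
        running_sum += float(np.sum(piece))
        running_n += piece.size
    return np.concatenate(parts), running_sum, running_n


def splice_signal(library: EpochLibrary, schedule: Sequence[tuple[int, float]],
                  dt: float | None = None, seed: int | None = 0,
                  mean_tol: float = 0.01) -> ExtrinsicSignal:
    """Concatenate SEE epochs with non-spiking gaps per ``schedule``.

    ``schedule`` is a list of (see_index, gap_ms) pairs: each SEE epoch is
    appended, followed by a gap of the given length filled from the non-spiking
    pool (drawn without replacement, greedily steering the overall mean toward
    Ic; interiors are never rescaled).  The final mean must lie within
    ``mean_tol`` (relative) of Ic, else a ValueError reports the deficit.
    Onset times of each SEE (start of its excerpt) are recorded in meta.
    """
    if dt is None:
        dt = library.dt
    if not np.isclose(dt, library.dt):
        raise ValueError("all epochs share the library dt grid")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(library.nonspiking)))
    used: list = []
    parts: list[np.ndarray] = []
    onsets: list[float] = []
    run_sum, run_n = 0.0, 0
    items = [(library.sees[i], int(round(g / dt))) for i, g in schedule]
    see_sums = np.array([float(np.sum(e)) for e, _ in items])
    see_ns = np.array([e.size for e, _ in items])
    gap_ns = np.array([g for _, g in items])
    for k, (epoch, n_gap) in enumerate(items):
        onsets.append(run_n * dt)
        parts.append(epoch)
        run_sum += see_sums[k]
        run_n += int(see_ns[k])
        if n_gap > 0:
            gap, run_sum, run_n = _fill_gap(
                n_gap, library.nonspiking, order, used, run_sum, run_n, library.Ic,
                future_sum=float(see_sums[k + 1:].sum()),
                future_n=int(see_ns[k + 1:].sum()),
                future_gap=int(gap_ns[k + 1:].sum()))
            parts.append(gap)
    values = np.concatenate(parts)
    mean = float(np.mean(values))
    if abs(mean - library.Ic) > mean_tol * abs(library.Ic):
        raise ValueError(
            f"mean preservation infeasible: spliced mean {mean:.4f} deviates from "
            f"Ic={library.Ic:.4f} by more than {mean_tol:.0%}")
    meta = {"Ic": library.Ic, "construction": "spliced", "seed": seed,
            "schedule": [(int(i), float(g)) for i, g in schedule],
            "onsets": onsets}
    return ExtrinsicSignal(dt=dt, values=values, meta=meta)


def insert_sta_copies(sta_waveform: np.ndarray, library: EpochLibrary, n_copies: int,
                      gaps: Sequence[float], dt: float | None = None,
                      seed: int | None = 0, mean_tol: float = 0.01) -> ExtrinsicSignal:
    """Signal of ``n_copies`` of an STA waveform separated by non-spiking background.

    ``gaps`` gives the background length (ms) preceding each copy (cycled if
    shorter than n_copies).  Gap filling and the mean-preservation contract are
    as in :func:`splice_signal`.  meta['onsets'] records the start time of each
    inserted copy; the excised window at each onset equals the waveform exactly.
    """
    if dt is None:
        dt = library.dt
    sta_waveform = np.asarray(sta_waveform, dtype=float)
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(library.nonspiking)))
    used: list = []
    parts: list[np.ndarray] = []
    onsets: list[float] = []
    run_sum, run_n = 0.0, 0
    sta_sum = float(np.sum(sta_waveform))
    gap_ns = [int(round(gaps[k % len(gaps)] / dt)) for k in range(n_copies)]
    for k in range(n_copies):
        n_gap = gap_ns[k]
        if n_gap > 0:
            n_future_copies = n_copies - k
            gap, run_sum, run_n = _fill_gap(
                n_gap, library.nonspiking, order, used, run_sum, run_n, library.Ic,
                future_sum=sta_sum * n_future_copies,
                future_n=sta_waveform.size * n_future_copies,
                future_gap=int(sum(gap_ns[k + 1:])))
            parts.append(gap)
        onsets.append(run_n * dt)
        parts.append(sta_waveform)
        run_sum += sta_sum
        run_n += sta_waveform.size
    values = np.concatenate(parts)
    mean = float(np.mean(values))
    if abs(mean - library.Ic) > mean_tol * abs(library.Ic):
        raise ValueError(
            f"mean preservation infeasible: mean {mean:.4f} vs Ic={library.Ic:.4f}")
    meta = {"Ic": library.Ic, "construction": "sta-inserted", "seed": seed,
            "onsets": onsets, "n_copies": n_copies}
    return ExtrinsicSignal(dt=dt, values=values, meta=meta)


def power_spectrum(signal: ExtrinsicSignal | np.ndarray, dt: float | None = None,
                   window: str = "boxcar"):
    """One-sided periodogram of the mean-removed signal.

    Returns (frequency, power) with frequency in kHz (cycles/ms) up to the
    Nyquist limit 1/(2 dt); power is a density so that sum(P) * df equals the
    variance of the mean-removed samples (Parseval).
    """
    if isinstance(signal, ExtrinsicSignal):
        x, dt = signal.values, signal.dt
    else:
        x = np.asarray(signal, dtype=float)
        if dt is None:
            raise ValueError("dt required for bare arrays")
    f, p = periodogram(x, fs=1.0 / dt, window=window, detrend="constant")
    return f, p
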