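"""Fixed-step RK4 integration of the Morris–Lecar flow with additive noise.

Per step n (dt = 1/30 ms by default), the deterministic flow is advanced with a
classical RK4 update whose voltage slope is (F(v,w) + I_det(t_n)) / c, using the
grid value of the current for all four slopes; then the per-step stochastic
kick is added to v only:

    v_{n+1} = RK4(v_n, w_n; I_det) + delta1 * sqrt(dt) * Z_n + kick_ext[n]
    w_{n+1} = RK4 w-component

Two noise conventions are supported:

* ``mode='increment'`` (default): both noise terms are unit-variance
  discrete-time sequences scaled by their coefficients and applied as per-step
  voltage drifts, un-divided by c,

      kick[n] = (delta1 * Z_n + (Iext[n] - Ic)) * dt,

  with Z_n iid standard normal per trial and Iext - Ic the frozen fluctuation
  (per-sample SD delta2 for a normalized filtered signal).  The deterministic
  slopes see I_det = Ibias + Ic.  This per-step-drift convention is tied to the
  fixed working step dt = 1/30 ms: delta1 and delta2 are commensurate knobs on
  the same voltage-drive scale, which is the calibration under which the
  frozen-noise reliability phenomena of this model regime appear (constant
  input unreliable, frozen fluctuating input reliable, a correlation-time
  optimum for the Hopf-side preset).
* ``mode='current'``: the conventional SDE reading — the whole signal enters
  the deterministic slopes, I_det(t) = Ibias + Iext(t), and the intrinsic term
  is a white-noise current, kick[n] = (delta1 / c) * sqrt(dt) * Z_n.  In this
  mode the weak solution converges as dt is refined, but at the delta values
  used here the extrinsic fluctuation is too weak (by the factor c) to shape
  spike timing.

Intrinsic noise is per-trial: each trial draws an independent stream spawned
from the ensemble master seed; the extrinsic signal is shared (frozen).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import MLParameters, NeuronState
from .signals import ExtrinsicSignal

__all__ = ["Trajectory", "RasterSet", "integrate_trial", "run_ensemble",
           "deterministic_trajectory"]

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard runtime expectation
    def njit(*a, **k):
        if a and callable(a[0]):
            return a[0]
        return lambda f: f


@njit(cache=True)
def _rk4_noise_core(v0, w0, dt, i_det, kick, c, gCa, gK, gL, vCa, vK, vL,
                    v1, v2, v3, v4, phi):
    """Advance (v, w) over len(i_det) steps; returns arrays of length n+1.

    ``i_det`` is the deterministic current per step (held over the step),
    ``kick`` the total stochastic voltage increment per step (intrinsic plus,
    in increment mode, the frozen extrinsic drift).
    """
    n = i_det.size
    v_out = np.empty(n + 1)
    w_out = np.empty(n + 1)
    v = v0
    w = w0
    v_out[0] = v
    w_out[0] = w
    for i in range(n):
        I = i_det[i]
        # k1
        m = 0.5 * (1.0 + np.tanh((v - v1) / v2))
        winf = 0.5 * (1.0 + np.tanh((v - v3) / v4))
        lam = phi * np.cosh((v - v3) / (2.0 * v4))
        kv1 = (-gCa * m * (v - vCa) - gK * w * (v - vK) - gL * (v - vL) + I) / c
        kw1 = lam * (winf - w)
        # k2
        va = v + 0.5 * dt * kv1
        wa = w + 0.5 * dt * kw1
        m = 0.5 * (1.0 + np.tanh((va - v1) / v2))
        winf = 0.5 * (1.0 + np.tanh((va - v3) / v4))
        lam = phi * np.cosh((va - v3) / (2.0 * v4))
        kv2 = (-gCa * m * (va - vCa) - gK * wa * (va - vK) - gL * (va - vL) + I) / c
        kw2 = lam * (winf - wa)
        # k3
        va = v + 0.5 * dt * kv2
        wa = w + 0.5 * dt * kw2
        m = 0.5 * (1.0 + np.tanh((va - v1) / v2))
        winf = 0.5 * (1.0 + np.tanh((va - v3) / v4))
        lam = phi * np.cosh((va - v3) / (2.0 * v4))
        kv3 = (-gCa * m * (va - vCa) - gK * wa * (va - vK) - gL * (va - vL) + I) / c
        kw3 = lam * (winf - wa)
        # k4
        va = v + dt * kv3
        wa = w + dt * kw3
        m = 0.5 * (1.0 + np.tanh((va - v1) / v2))
        winf = 0.5 * (1.0 + np.tanh((va - v3) / v4))
        lam = phi * np.cosh((va - v3) / (2.0 * v4))
        kv4 = (-gCa * m * (va - vCa) - gK * wa * (va - vK) - gL * (va - vL) + I) / c
        kw4 = lam * (winf - wa)

        v = v + (dt / 6.0) * (kv1 + 2.0 * kv2 + 2.0 * kv3 + kv4) + kick[i]
        w = w + (dt / 6.0) * (kw1 + 2.0 * kw2 + 2.0 * kw3 + kw4)
        v_out[i + 1] = v
        w_out[i + 1] = w
    return v_out, w_out


def _params_tuple(p: MLParameters):
    return (p.c, p.gCa, p.gK, p.gL, p.vCa, p.vK, p.vL,
            p.v1, p.v2, p.v3, p.v4, p.phi)


@dataclass
class Trajectory:
    """One simulated path: uniform-dt arrays of t, v, w plus provenance."""

    dt: float
    t: np.ndarray
    v: np.ndarray
    w: np.ndarray
    x0: NeuronState
    intrinsic_seed: object = None
    signal_meta: dict = field(default_factory=dict)

    def state_at(self, time: float) -> tuple[float, float]:
        """Linearly interpolated (v, w) at an arbitrary time."""
        return (float(np.interp(time, self.t, self.v)),
                float(np.interp(time, self.t, self.w)))


@dataclass
class RasterSet:
    """Spike-time ensemble from N trials under one frozen extrinsic signal."""

    n_trials: int
    dt: float
    t_end: float
    burn_in: float
    spike_times: list        # per trial: sorted array of threshold-crossing times, ms
    w_at_spikes: list        # per trial: w interpolated at each crossing
    master_seed: object
    trial_seeds: list
    signal: ExtrinsicSignal | None = None
    trajectories: list | None = None
    params: MLParameters | None = None

    def analysis_window(self) -> tuple[float, float]:
        return (self.burn_in, self.t_end)

    def spike_counts(self) -> np.ndarray:
        return np.array([len(s) for s in self.spike_times])

    def to_json(self) -> str:
        import json
        return json.dumps({
            "n_trials": self.n_trials, "dt": self.dt, "t_end": self.t_end,
            "burn_in": self.burn_in, "master_seed": self.master_seed,
            "trial_seeds": [int(s) for s in self.trial_seeds],
            "spike_times": [list(map(float, s)) for s in self.spike_times],
            "w_at_spikes": [list(map(float, s)) for s in self.w_at_spikes],
        }, indent=1)

    @classmethod
    def from_json(cls, s: str) -> "RasterSet":
        import json
        d = json.loads(s)
        return cls(n_trials=d["n_trials"], dt=d["dt"], t_end=d["t_end"],
                   burn_in=d["burn_in"],
                   spike_times=[np.asarray(x) for x in d["spike_times"]],
                   w_at_spikes=[np.asarray(x) for x in d["w_at_spikes"]],
                   master_seed=d["master_seed"], trial_seeds=d["trial_seeds"])


def _kick_arrays(params: MLParameters, signal: ExtrinsicSignal, mode: str,
                 rng: np.random.Generator | None) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic current per step and stochastic voltage kick per step."""
    dt = signal.dt
    n = signal.n
    if mode == "increment":
        i_det = np.full(n, params.Ibias + signal.Ic)
        kick = signal.fluctuation() * dt
        if params.delta1 != 0.0 and rng is not None:
            kick = kick + params.delta1 * dt * rng.standard_normal(n)
    elif mode == "current":
        i_det = params.Ibias + signal.values
        kick = np.zeros(n)
        if params.delta1 != 0.0 and rng is not None:
            kick = kick + (params.delta1 / params.c) * np.sqrt(dt) * rng.standard_normal(n)
    else:
        raise ValueError("mode must be 'increment' or 'current'")
    return i_det, kick


def integrate_trial(params: MLParameters, signal: ExtrinsicSignal,
                    x0: NeuronState | tuple, intrinsic_seed=None,
                    mode: str = "increment") -> Trajectory:
    """Integrate one trial under a frozen signal with its own intrinsic stream.

    With delta1 = 0 the result is independent of ``intrinsic_seed`` and equals
    the deterministic RK4 solution driven by the signal.  Raises on numerical
    blow-up (NaN/overflow), reporting the first bad step.
    """
    v0, w0 = (x0.v, x0.w) if isinstance(x0, NeuronState) else (float(x0[0]), float(x0[1]))
    rng = None
    if params.delta1 != 0.0:
        rng = (intrinsic_seed if isinstance(intrinsic_seed, np.random.Generator)
               else np.random.default_rng(intrinsic_seed))
    i_det, kick = _kick_arrays(params, signal, mode, rng)
    v, w = _rk4_noise_core(v0, w0, signal.dt, i_det, kick, *_params_tuple(params))
    if not np.all(np.isfinite(v)):
        bad = int(np.argmax(~np.isfinite(v)))
        raise FloatingPointError(f"non-finite voltage at step {bad} (t={bad * signal.dt:.3f} ms)")
    t = np.arange(v.size) * signal.dt
    return Trajectory(dt=signal.dt, t=t, v=v, w=w,
                      x0=NeuronState(v0, min(max(w0, 0.0), 1.0)),
                      intrinsic_seed=intrinsic_seed, signal_meta=dict(signal.meta))


def deterministic_trajectory(params: MLParameters, I_total: float, x0,
                             duration: float, dt: float = 1.0 / 30.0) -> Trajectory:
    """Noise-free RK4 path under a constant total current (helper for dynamics)."""
    n = int(round(duration / dt))
    v0, w0 = (x0.v, x0.w) if isinstance(x0, NeuronState) else (float(x0[0]), float(x0[1]))
    i_det = np.full(n, I_total)
    kick = np.zeros(n)
    v, w = _rk4_noise_core(v0, w0, dt, i_det, kick, *_params_tuple(params))
    if not np.all(np.isfinite(v)):
        bad = int(np.argmax(~np.isfinite(v)))
        raise FloatingPointError(f"non-finite voltage at step {bad}")
    t = np.arange(v.size) * dt
    return Trajectory(dt=dt, t=t, v=v, w=w, x0=NeuronState(v0, min(max(w0, 0.0), 1.0)))


def run_ensemble(params: MLParameters, signal: ExtrinsicSignal, n_trials: int,
                 master_seed: int = 0, x0: NeuronState | tuple | None = None,
                 burn_in: float = 500.0, mode: str = "increment",
                 vth: float = -20.0, min_separation: float = 30.0,
                 keep_trajectories: bool = False) -> RasterSet:
    """Run N trials under one frozen signal; collect spike times and w at threshold.

    Each trial uses an independent intrinsic stream spawned from ``master_seed``
    (SeedSequence substreams, recorded per trial).  Spikes are upward crossings
    of ``vth`` within the post-burn-in analysis window; the value of w at each
    crossing is interpolated and stored alongside.  The default initial state is
    the most stable fixed point of the deterministic system at I = Ibias + Ic.
    """
    if n_trials < 2:
        raise ValueError("need at least 2 trials")
    from .metrics import detect_spikes, SpikeDetectionConfig, values_at_times

    if x0 is None:
        x0 = resting_state(params)
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(n_trials)
    trial_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    cfg = SpikeDetectionConfig(vth=vth, min_separation=min_separation)
    spikes, w_vals, trajs = [], [], []
    for child in children:
        traj = integrate_trial(params, signal, x0,
                               intrinsic_seed=np.random.default_rng(child), mode=mode)
        times = detect_spikes(traj.t, traj.v, cfg)
        times = times[times >= burn_in]
        w_at = values_at_times(traj.t, traj.w, times)
        spikes.append(times)
        w_vals.append(w_at)
        if keep_trajectories:
            trajs.append(traj)
    return RasterSet(
        n_trials=n_trials, dt=signal.dt, t_end=signal.duration, burn_in=burn_in,
        spike_times=spikes, w_at_spikes=w_vals, master_seed=master_seed,
        trial_seeds=trial_seeds, signal=signal,
        trajectories=trajs if keep_trajectories else None, params=params)


def resting_state(params: MLParameters, I_total: float | None = None) -> NeuronState:
    """Most stable deterministic fixed point at I (default Ibias + Ic)."""
    from .dynamics import find_fixed_points

    if I_total is None:
        I_total = params.I_rest
    fps = find_fixed_points(params, I_total)
    stable = [f for f in fps if f.stability.startswith("stable")]
    rec = stable[0] if stable else fps[0]
    return rec.state
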