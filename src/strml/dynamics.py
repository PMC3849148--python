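"""Deterministic phase-plane structure of the Morris–Lecar model.

Fixed points and their stability, linearized (subthreshold) frequencies,
bifurcation detection in the bias current (saddle-node on invariant circle,
subcritical Hopf, fold of the periodic branch), limit-cycle frequencies from
Poincaré return times, f-I curves, and the threshold manifolds:

* Type I: the *slow manifold* — invariant sets of the middle saddle point,
  traced by integrating from small offsets along its eigenvectors (forward in
  time along the unstable directions, backward along the stable ones).
* Type II: the *pseudo-slow manifold* — there is a single stable fixed point,
  but the excitable regime has a sharp separatrix between direct decay and a
  full action-potential excursion; it is located by bisecting spike/no-spike
  outcomes in w along vertical transversal lines and assembled as a polyline.

All currents are total instantaneous deterministic currents in uA/cm^2;
frequencies are in kHz (cycles/ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model import MLParameters, NeuronState, gating, ionic_current, jacobian, rhs
from .integrate import deterministic_trajectory
from .metrics import detect_spikes, SpikeDetectionConfig

__all__ = [
    "FixedPointRecord",
    "BifurcationScan",
    "ManifoldSnapshot",
    "find_fixed_points",
    "intrinsic_frequency",
    "detect_equilibrium_bifurcations",
    "limit_cycle_frequency",
    "detect_fold_of_cycles",
    "manifold_snapshot",
    "scan_bifurcation",
    "spikes_from_state",
]

V_SEARCH = (-85.0, 60.0)     # mV window guaranteed to contain all physical equilibria
V_SPIKE = 0.0                # a trajectory reaching v > 0 mV counts as a spike
SPIKE_HORIZON = 500.0        # ms allowed for the excursion in classification


@dataclass(frozen=True)
class FixedPointRecord:
    """An equilibrium with its eigenvalues (1/ms) and stability class."""

    state: NeuronState
    eigenvalues: tuple
    stability: str  # stable-node | stable-focus | saddle | unstable-node | unstable-focus

    @property
    def is_saddle(self) -> bool:
        return self.stability == "saddle"


@dataclass
class ManifoldSnapshot:
    """Threshold curve in the (v, w) plane at one instantaneous current.

    kind='slow': saddle invariant sets (Type I); branches maps a label such as
    'unstable+' to its polyline.  kind='pseudo-slow': simulated separatrix
    (Type II); ``polyline`` is the ordered (v, w) separatrix.
    """

    kind: str
    I_inst: float
    polyline: np.ndarray
    branches: dict = field(default_factory=dict)

    def w_at(self, v: float) -> float:
        pl = self.polyline[np.argsort(self.polyline[:, 0])]
        return float(np.interp(v, pl[:, 0], pl[:, 1]))


def _classify(eigs: np.ndarray) -> str:
    if np.iscomplex(eigs).any():
        return "stable-focus" if eigs.real.max() < 0 else "unstable-focus"
    lo, hi = np.sort(eigs.real)
    if hi < 0:
        return "stable-node"
    if lo > 0:
        return "unstable-node"
    return "saddle"


def find_fixed_points(params: MLParameters, I: float,
                      resolution: float = 0.25) -> list[FixedPointRecord]:
    """All equilibria at total current I, sorted by v.

    At equilibrium w is slaved to w_inf(v), so the search reduces to the 1-D
    root problem of the net membrane current over v in [-85, 60] mV: sign
    changes are bracketed at ``resolution`` and polished with Brent's method.
    Raises if no root is found (does not occur for physical currents).
    """
    if not np.isfinite(I):
        raise ValueError("I must be finite")

    def h(v: float) -> float:
        _, w_inf, _ = gating(v, params)
        return float(ionic_current(v, w_inf, params) + I)

    vs = np.arange(V_SEARCH[0], V_SEARCH[1] + resolution / 2, resolution)
    hv = np.array([h(v) for v in vs])
    records = []
    for k in range(vs.size - 1):
        if hv[k] == 0.0:
            root = float(vs[k])
        elif hv[k] * hv[k + 1] < 0:
            root = brentq(h, vs[k], vs[k + 1], xtol=1e-12)
        else:
            continue
        _, w_inf, _ = gating(root, params)
        state = NeuronState(root, float(w_inf))
        eigs = np.linalg.eigvals(jacobian(state, I, params))
        records.append(FixedPointRecord(state=state, eigenvalues=tuple(eigs),
                                        stability=_classify(eigs)))
    if not records:
        raise RuntimeError(f"fixed-point search failed at I={I}")
    return sorted(records, key=lambda r: r.state.v)


def intrinsic_frequency(params: MLParameters, I: float,
                        record: FixedPointRecord | None = None) -> float | None:
    """Linearized frequency |Im(eigenvalue)| / (2 pi) in kHz at a fixed point.

    By default the unique fixed point (or the stable focus, if several exist)
    is used; pass ``record`` to select one explicitly.  Returns None when the
    eigenvalues are real (no subthreshold oscillation).
    """
    if record is None:
        fps = find_fixed_points(params, I)
        if len(fps) == 1:
            record = fps[0]
        else:
            foci = [f for f in fps if f.stability == "stable-focus"]
            if not foci:
                foci = [f for f in fps if "focus" in f.stability]
            if not foci:
                return None
            record = foci[0]
    eigs = np.asarray(record.eigenvalues)
    im = float(np.abs(eigs.imag).max())
    if im == 0.0:
        return None
    return im / (2.0 * np.pi)


def _upper_re(params: MLParameters, I: float) -> float:
    """Leading real part of the eigenvalues of the uppermost (largest-v) equilibrium."""
    rec = find_fixed_points(params, I)[-1]
    return float(np.asarray(rec.eigenvalues).real.max())


def detect_equilibrium_bifurcations(params: MLParameters,
                                    I_range: tuple[float, float],
                                    tol: float = 0.005,
                                    grid_step: float = 0.25) -> dict:
    """Locate the SNIC and Hopf currents inside ``I_range`` by bisection.

    The SNIC is found as the collision of the stable node and the saddle — the
    current at which the fixed-point count drops from 3 to 1.  The Hopf is the
    sign change of Re(eigenvalue) on the uppermost equilibrium branch, accepted
    only where the eigenvalues are complex.  Absent events are reported as
    None, never as zero.  Tolerances are well below 0.01 uA/cm^2.
    """
    lo, hi = I_range
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    out: dict = {"I_SNIC": None, "I_HB": None}

    counts = [len(find_fixed_points(params, I)) for I in grid]
    for k in range(len(grid) - 1):
        if counts[k] == 3 and counts[k + 1] == 1:
            a, b = grid[k], grid[k + 1]
            while b - a > tol:
                mid = 0.5 * (a + b)
                if len(find_fixed_points(params, mid)) == 3:
                    a = mid
                else:
                    b = mid
            out["I_SNIC"] = 0.5 * (a + b)
            break

    res = [_upper_re(params, I) for I in grid]
    for k in range(len(grid) - 1):
        if res[k] * res[k + 1] < 0:
            I_hb = brentq(lambda I: _upper_re(params, I), grid[k], grid[k + 1],
                          xtol=min(tol, 1e-4))
            eigs = np.asarray(find_fixed_points(params, I_hb)[-1].eigenvalues)
            if np.abs(eigs.imag).max() > 0:
                out["I_HB"] = float(I_hb)
                break
    return out


def spikes_from_state(params: MLParameters, I: float, x0,
                      duration: float = SPIKE_HORIZON, dt: float = 1.0 / 30.0) -> bool:
    """True if the deterministic trajectory from x0 reaches v > 0 mV within duration."""
    traj = deterministic_trajectory(params, I, x0, duration, dt)
    return bool(np.max(traj.v) > V_SPIKE)


def limit_cycle_frequency(params: MLParameters, I: float,
                          x0=None, transient: float = 1000.0,
                          measure: float = 3000.0, section: float = -20.0,
                          dt: float = 1.0 / 30.0,
                          spread_tol: float = 0.005) -> float | None:
    """Frequency (kHz) of the attracting periodic orbit at total current I.

    The period is measured from successive upward crossings of the Poincaré
    section v = -20 mV after a transient discard.  Returns None when the
    trajectory settles to a fixed point (fewer than 3 crossings in the
    measurement window).  A relative spread of the successive periods above
    ``spread_tol`` raises (non-convergent estimate).
    """
    if x0 is None:
        # start well away from any rest state so an attracting cycle is reached
        rec = find_fixed_points(params, I)[-1]
        x0 = (rec.state.v + 40.0, rec.state.w)
        x0 = (min(x0[0], 50.0), x0[1])
    traj = deterministic_trajectory(params, I, x0, transient + measure, dt)
    sel = traj.t >= transient
    crossings = detect_spikes(traj.t[sel], traj.v[sel],
                              SpikeDetectionConfig(vth=section, min_separation=dt * 2))
    if crossings.size < 3:
        return None
    periods = np.diff(crossings)
    spread = (periods.max() - periods.min()) / periods.mean()
    if spread > spread_tol:
        raise RuntimeError(
            f"period estimate not converged at I={I}: spread {spread:.2%}")
    return float(1.0 / periods.mean())


def detect_fold_of_cycles(params: MLParameters, I_range: tuple[float, float],
                          tol: float = 0.01, coarse_step: float = 0.25,
                          settle: float = 4000.0, check: float = 2000.0,
                          dt: float = 1.0 / 30.0) -> float | None:
    """Smallest current at which a stable limit cycle persists (fold of cycles).

    The stable periodic branch is continued downward in I from the top of
    ``I_range``: at each step the end state of the previous oscillatory run is
    reused as the initial condition, and the oscillation counts as sustained if
    v exceeds 0 mV within the final ``check`` ms of a ``settle`` + ``check``
    window.  The fold is then bisected between the last surviving and first
    failing currents.  Returns None when no sustained oscillation exists
    anywhere in the range (no fold on the periodic branch).
    """
    lo, hi = I_range

    def run(I: float, x0):
        traj = deterministic_trajectory(params, I, x0, settle + check, dt)
        tail = traj.v[traj.t >= settle]
        sustained = bool(np.max(tail) > V_SPIKE)
        return sustained, (traj.v[-1], min(max(traj.w[-1], 0.0), 1.0))

    rec = find_fixed_points(params, hi)[-1]
    state = (min(rec.state.v + 40.0, 50.0), rec.state.w)
    sustained, state = run(hi, state)
    if not sustained:
        return None

    I_alive, alive_state = hi, state
    I_dead = None
    I = hi - coarse_step
    while I >= lo - 1e-12:
        sustained, end_state = run(I, alive_state)
        if sustained:
            I_alive, alive_state = I, end_state
        else:
            I_dead = I
            break
        I -= coarse_step
    if I_dead is None:
        return None  # branch persists through the whole range: fold not bracketed

    a, b = I_dead, I_alive
    while b - a > tol:
        mid = 0.5 * (a + b)
        sustained, end_state = run(mid, alive_state)
        if sustained:
            b, alive_state = mid, end_state
        else:
            a = mid
    return float(0.5 * (a + b))


def _trace_branch(params: MLParameters, I: float, x0: np.ndarray,
                  direction: float, t_max: float = 600.0) -> np.ndarray:
    """Integrate the flow (direction=+1) or its reversal (-1) until leaving the window."""

    def fun(_t, y):
        dv, dw = rhs((y[0], y[1]), I, params)
        return [direction * dv, direction * dw]

    def leave(_t, y):
        return min(y[0] - (V_SEARCH[0] - 5), (80.0 - y[0]),
                   y[1] + 0.05, 1.05 - y[1])
    leave.terminal = True
    leave.direction = -1

    sol = solve_ivp(fun, (0.0, t_max), x0, rtol=1e-8, atol=1e-10,
                    max_step=1.0, events=leave, dense_output=False)
    return np.column_stack([sol.y[0], sol.y[1]])


def manifold_snapshot(params: MLParameters, I_inst: float, kind: str,
                      eps: float = 1e-4, w_tol: float = 1e-4,
                      v_grid: np.ndarray | None = None) -> ManifoldSnapshot:
    """Threshold manifold in the phase plane at instantaneous current I_inst.

    kind='slow' requires a saddle (three equilibria): its four invariant-set
    branches are traced from +-eps eigenvector offsets, stable sets backward in
    time, unstable forward; the polyline returned is the stable set (the
    incoming pair), which is the separatrix, with the saddle itself on it.
    kind='pseudo-slow' bisects spike/decay outcomes in w (tolerance ``w_tol``)
    along vertical lines at ``v_grid`` and joins the points.
    """
    if kind == "slow":
        fps = find_fixed_points(params, I_inst)
        saddles = [f for f in fps if f.is_saddle]
        if not saddles:
            raise ValueError(f"no saddle exists at I={I_inst}; slow manifold undefined")
        saddle = saddles[0]
        J = jacobian(saddle.state, I_inst, params)
        eigvals, eigvecs = np.linalg.eig(J)
        x_s = saddle.state.as_array()
        branches = {}
        stable_pts = [x_s.reshape(1, 2)]
        for k in range(2):
            lam = eigvals[k].real
            vec = eigvecs[:, k].real
            vec = vec / np.linalg.norm(vec)
            # seed offset: eps in units of the phase-plane scale (~50 mV x 0.5)
            off = vec * eps * 50.0
            label = "unstable" if lam > 0 else "stable"
            direction = 1.0 if lam > 0 else -1.0
            for sgn, suffix in ((1.0, "+"), (-1.0, "-")):
                pts = _trace_branch(params, I_inst, x_s + sgn * off, direction)
                branches[f"{label}{suffix}"] = pts
                if label == "stable":
                    stable_pts.append(pts)
        # separatrix polyline: incoming (stable) branches joined through the saddle
        minus = branches["stable-"][::-1]
        plus = branches["stable+"]
        polyline = np.vstack([minus, x_s.reshape(1, 2), plus])
        return ManifoldSnapshot(kind="slow", I_inst=I_inst, polyline=polyline,
                                branches=branches)

    if kind != "pseudo-slow":
        raise ValueError("kind must be 'slow' or 'pseudo-slow'")

    fps = find_fixed_points(params, I_inst)
    stable = [f for f in fps if f.stability.startswith("stable")]
    if not stable:
        raise ValueError(f"system is not excitable at I={I_inst}: no stable state")
    rest = stable[0].state
    if v_grid is None:
        v_grid = np.linspace(rest.v - 2.0, 5.0, 25)
    pts = []
    for v in v_grid:
        lo_w, hi_w = 0.0, 1.0
        if not spikes_from_state(params, I_inst, (v, lo_w)):
            continue  # even w=0 decays: line does not cross the separatrix
        if spikes_from_state(params, I_inst, (v, hi_w)):
            continue  # even w=1 spikes: no crossing on this line
        while hi_w - lo_w > w_tol:
            mid = 0.5 * (lo_w + hi_w)
            if spikes_from_state(params, I_inst, (v, mid)):
                lo_w = mid
            else:
                hi_w = mid
        pts.append((v, 0.5 * (lo_w + hi_w)))
    if not pts:
        raise ValueError(f"no separatrix found at I={I_inst}; system may not be excitable")
    return ManifoldSnapshot(kind="pseudo-slow", I_inst=I_inst,
                            polyline=np.asarray(pts))


@dataclass
class BifurcationScan:
    """Equilibrium branches with stability, special points, and f-I samples."""

    I_grid: np.ndarray
    branches: list                 # rows: (I, v, w, stability)
    special: dict                  # {'I_SNIC':…, 'I_HB':…, 'I_SN_of_cycles':…}
    f_I: list                      # rows: (I, frequency kHz)

    def to_frame(self):
        import pandas as pd
        return (pd.DataFrame(self.branches, columns=["I", "v", "w", "stability"]),
                pd.DataFrame(self.f_I, columns=["I", "frequency_kHz"]))


def scan_bifurcation(params: MLParameters, I_min: float, I_max: float,
                     n_grid: int = 81, with_f_I: bool = True,
                     f_I_points: int = 12) -> BifurcationScan:
    """Dense scan of equilibria plus bifurcation detection and an f-I curve."""
    I_grid = np.linspace(I_min, I_max, n_grid)
    rows = []
    for I in I_grid:
        for rec in find_fixed_points(params, I):
            rows.append((float(I), rec.state.v, rec.state.w, rec.stability))
    special = detect_equilibrium_bifurcations(params, (I_min, I_max))
    special["I_SN_of_cycles"] = detect_fold_of_cycles(params, (I_min, I_max)) \
        if params.variant.value == "TypeII" else None
    f_rows = []
    if with_f_I:
        onset = special.get("I_SNIC") or special.get("I_SN_of_cycles") or I_min
        for I in np.linspace(onset + 0.05, I_max, f_I_points):
            try:
                f = limit_cycle_frequency(params, float(I))
            except RuntimeError:
                f = None
            if f is not None:
                f_rows.append((float(I), f))
    return BifurcationScan(I_grid=I_grid, branches=rows, special=special, f_I=f_rows)
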