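"""Deterministic Morris–Lecar core: gating functions, right-hand side, Jacobian, presets.

The Morris–Lecar membrane model is a two-variable conductance-based neuron:

    c dv/dt = -gCa m_inf(v)(v - vCa) - gK w (v - vK) - gL (v - vL) + I
      dw/dt = lambda(v) (w_inf(v) - w)

with instantaneous Ca2+ activation ``m_inf`` and a single recovery variable ``w``
(the K+ channel open probability).  Units throughout the package: time ms,
voltage mV, current density uA/cm^2, conductance mS/cm^2, capacitance uF/cm^2;
frequencies are therefore in kHz (cycles per ms).

Two parameter presets are provided.  ``TYPE_I`` sits near a saddle-node-on-
invariant-circle (SNIC) transition, where the firing rate grows continuously
from zero; ``TYPE_II`` sits near a subcritical Hopf / fold-of-cycles transition,
where oscillations appear at a finite frequency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from enum import Enum
from fractions import Fraction
from typing import Tuple

import numpy as np

__all__ = [
    "Variant",
    "MLParameters",
    "NeuronState",
    "TYPE_I",
    "TYPE_II",
    "preset",
    "gating",
    "rhs",
    "jacobian",
]


class Variant(str, Enum):
    """Excitability class of a preset (continuous vs. discontinuous f-I onset)."""

    TYPE_I = "TypeI"
    TYPE_II = "TypeII"


@dataclass(frozen=True)
class MLParameters:
    """Full parameter vector for one Morris–Lecar variant, noise settings included.

    Attributes
    ----------
    c : float
        Membrane capacitance, uF/cm^2.
    gCa, gK, gL : float
        Maximal conductances, mS/cm^2.
    vCa, vK, vL : float
        Reversal potentials, mV.
    v1, v2 : float
        Half-activation voltage and slope of the Ca2+ gate m_inf, mV.
    v3, v4 : float
        Half-activation voltage and slope of the K+ gate w_inf, mV.
    phi : float
        Rate scale of the w kinetics, 1/ms.
    Ibias : float
        Constant bias current, uA/cm^2 (the bifurcation parameter).
    Ic : float
        Mean of the extrinsic input current, uA/cm^2.
    delta1 : float
        Intrinsic (per-trial) white-noise coefficient, uA/cm^2.
    delta2 : float
        Extrinsic (frozen) noise coefficient, uA/cm^2.
    tau : float
        Correlation time of the alpha-filtered extrinsic noise, ms.
    variant : Variant
        Excitability class label.
    """

    c: float
    gCa: float
    gK: float
    gL: float
    vCa: float
    vK: float
    vL: float
    v1: float
    v2: float
    v3: float
    v4: float
    phi: float
    Ibias: float
    Ic: float
    delta1: float
    delta2: float
    tau: float
    variant: Variant

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("capacitance c must be positive")
        for name in ("gCa", "gK", "gL"):
            if getattr(self, name) <= 0:
                raise ValueError(f"conductance {name} must be positive")
        for name in ("v2", "v4", "phi", "tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    # -- plain-text round trip -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["variant"] = self.variant.value
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "MLParameters":
        d = dict(d)
        d["variant"] = Variant(d["variant"])
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "MLParameters":
        return cls.from_dict(json.loads(s))

    def with_(self, **kw) -> "MLParameters":
        """Return a copy with selected fields replaced."""
        return replace(self, **kw)

    @property
    def I_rest(self) -> float:
        """Mean total deterministic current Ibias + Ic, uA/cm^2."""
        return self.Ibias + self.Ic


@dataclass(frozen=True)
class NeuronState:
    """Phase-plane point: membrane voltage v (mV) and K+ gate w (dimensionless)."""

    v: float
    w: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.w <= 1.0):
            raise ValueError(f"w must lie in [0, 1], got {self.w}")

    def as_array(self) -> np.ndarray:
        return np.array([self.v, self.w], dtype=float)


# phi for the Type I preset is the exact rational 1/15 per ms
_PHI_I = float(Fraction(1, 15))

TYPE_I = MLParameters(
    c=20.0, gCa=4.4, gK=8.0, gL=2.0,
    vCa=120.0, vK=-84.0, vL=-60.0,
    v1=-1.2, v2=18.0, v3=12.0, v4=17.4,
    phi=_PHI_I, Ibias=33.0, Ic=4.3,
    delta1=2.0, delta2=0.91, tau=7.0,
    variant=Variant.TYPE_I,
)

TYPE_II = MLParameters(
    c=20.0, gCa=5.6, gK=5.0, gL=3.0,
    vCa=120.0, vK=-84.0, vL=-60.0,
    v1=-1.2, v2=18.0, v3=-4.5, v4=15.0,
    phi=0.04, Ibias=63.0, Ic=4.1,
    delta1=5.0, delta2=1.64, tau=3.0,
    variant=Variant.TYPE_II,
)


def preset(variant: str | Variant) -> MLParameters:
    """Look up a preset by name ('TypeI'/'TypeII', case-insensitive, I/II also ok)."""
    if isinstance(variant, Variant):
        return TYPE_I if variant is Variant.TYPE_I else TYPE_II
    key = str(variant).lower().replace("_", "").replace("-", "")
    if key in ("typei", "type1", "i", "1"):
        return TYPE_I
    if key in ("typeii", "type2", "ii", "2"):
        return TYPE_II
    raise KeyError(f"unknown variant {variant!r}")


def gating(v, params: MLParameters):
    """Gating curves at voltage v: (m_inf, w_inf, lambda_rate).

    m_inf(v) = 0.5 (1 + tanh((v - v1)/v2))
    w_inf(v) = 0.5 (1 + tanh((v - v3)/v4))
    lambda(v) = phi cosh((v - v3)/(2 v4))     [1/ms]
    """
    v = np.asarray(v, dtype=float)
    m_inf = 0.5 * (1.0 + np.tanh((v - params.v1) / params.v2))
    w_inf = 0.5 * (1.0 + np.tanh((v - params.v3) / params.v4))
    lam = params.phi * np.cosh((v - params.v3) / (2.0 * params.v4))
    return m_inf, w_inf, lam


def ionic_current(v, w, params: MLParameters):
    """Total ionic (membrane) current at (v, w), uA/cm^2, inward positive."""
    m_inf = 0.5 * (1.0 + np.tanh((np.asarray(v, float) - params.v1) / params.v2))
    return (
        -params.gCa * m_inf * (v - params.vCa)
        - params.gK * w * (v - params.vK)
        - params.gL * (v - params.vL)
    )


def rhs(state, I_total: float, params: MLParameters) -> Tuple[float, float]:
    """Time derivatives (dv/dt, dw/dt) at a state under total current I_total.

    ``I_total`` is the full instantaneous deterministic current (Ibias plus the
    deterministic extrinsic part).  dv/dt is returned already divided by c.
    Accepts a NeuronState or any (v, w) pair / arrays.
    """
    if isinstance(state, NeuronState):
        v, w = state.v, state.w
    else:
        v, w = state
    _, w_inf, lam = gating(v, params)
    dv = (ionic_current(v, w, params) + I_total) / params.c
    dw = lam * (w_inf - w)
    return dv, dw


def jacobian(state, I_total: float, params: MLParameters) -> np.ndarray:
    """Analytic 2x2 Jacobian of the deterministic flow at a state.

    Rows correspond to (dv/dt, dw/dt), columns to (v, w).  I_total enters only
    through the flow, not the derivatives, but is kept in the signature for
    symmetry with :func:`rhs`.
    """
    if isinstance(state, NeuronState):
        v, w = state.v, state.w
    else:
        v, w = state
    p = params
    x = (v - p.v1) / p.v2
    m_inf = 0.5 * (1.0 + np.tanh(x))
    dm_dv = 0.5 / (p.v2 * np.cosh(x) ** 2)

    y = (v - p.v3) / p.v4
    w_inf = 0.5 * (1.0 + np.tanh(y))
    dwinf_dv = 0.5 / (p.v4 * np.cosh(y) ** 2)

    z = (v - p.v3) / (2.0 * p.v4)
    lam = p.phi * np.cosh(z)
    dlam_dv = p.phi * np.sinh(z) / (2.0 * p.v4)

    dFv = (
        -p.gCa * (dm_dv * (v - p.vCa) + m_inf) - p.gK * w - p.gL
    ) / p.c
    dFw = -p.gK * (v - p.vK) / p.c
    dGv = dlam_dv * (w_inf - w) + lam * dwinf_dv
    dGw = -lam
    return np.array([[dFv, dFw], [dGv, dGw]], dtype=float)
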