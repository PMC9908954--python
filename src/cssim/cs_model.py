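"""Adaptive phenomenological model of campaniform sensillum (CS) discharge.

The model output y (interpreted as action potentials per second) is driven
by the bending load u relative to an internal adaptive threshold x that
chases u:

    y = max(0, a*(u - x) + c*u + d)
    tau * dx/dt = sign(u - x) * |u - x|**b

One adaptive mechanism reproduces the dynamic signatures of large CS:
power-law encoding of the rate of change of load, adaptation to tonic
loads, hysteresis under cyclic loading, and phasic "rebound" bursts when a
sustained load is released (because x has adapted below zero and the return
to zero reads as a load increase).

With b > 1 the gap e = u - x decays as a power law under constant input:
|e|(t) = (|e0|**(1-b) + (b-1) t / tau) ** (-1/(b-1)), never crossing u.
The integrator below uses this closed form per sample (zero-order hold on
u), so threshold updates are exact for the held input, not a numerical
approximation.

Four CS groups are modeled: 3 and 4 on the trochanterofemur, 6B and 6A on
the proximal tibia.  All share the same published parameters except group
6A's smaller offset magnitude, which gives it a lower tonic threshold
(-d/c) than 6B.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "CSParameters",
    "CSState",
    "CSTrace",
    "PRESETS",
    "GROUP_CHANNEL_MAP",
    "discharge_step",
    "simulate_discharge",
    "steady_state_discharge",
    "tonic_threshold",
    "group_bank",
]


@dataclass(frozen=True)
class CSParameters:
    """Constants of one CS group's discharge model.

    a : gain on the dynamic term (u - x)
    b : adaptation exponent (power law; > 0, and > 1 for the published fits)
    c : tonic gain on u
    d : offset (negative for all published groups, so small tonic loads are
        rectified away)
    tau : adaptation time constant, seconds
    """

    a: float
    b: float
    c: float
    d: float
    tau: float

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        if not self.b > 0:
            raise ValueError("b must be positive")

    def output(self, u: float, x: float) -> float:
        return max(0.0, self.a * (u - x) + self.c * u + self.d)


#: Published parameter sets, keyed by CS group name.  Groups 6B, 3 and 4
#: are identical; 6A differs only in d.
PRESETS: Dict[str, CSParameters] = {
    "6B": CSParameters(a=338.9952, b=2.2707, c=7.1531, d=-27.9311, tau=0.0250),
    "6A": CSParameters(a=338.9952, b=2.2707, c=7.1531, d=-17.9311, tau=0.0250),
    "3": CSParameters(a=338.9952, b=2.2707, c=7.1531, d=-27.9311, tau=0.0250),
    "4": CSParameters(a=338.9952, b=2.2707, c=7.1531, d=-27.9311, tau=0.0250),
}

#: Which strain channel feeds which CS group.
GROUP_CHANNEL_MAP: Dict[str, str] = {
    "3": "tf_axial",
    "4": "tf_transverse",
    "6B": "tib_axial",
    "6A": "tib_transverse",
}


@dataclass(frozen=True)
class CSState:
    """Instantaneous model state: input u, adaptive threshold x, output y."""

    u: float
    x: float
    y: float


@dataclass
class CSTrace:
    """Time-discretized realization of the model on a uniform grid."""

    t: np.ndarray
    u: np.ndarray
    x: np.ndarray
    y: np.ndarray
    group: Optional[str] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.t)
        if not (len(self.u) == len(self.x) == len(self.y) == n):
            raise ValueError("t, u, x, y must have equal length")
        if n > 1:
            dt = np.diff(self.t)
            if not (np.all(dt > 0) and np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12)):
                raise ValueError("t must be strictly increasing with constant step")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "u": self.u, "x": self.x, "y": self.y})


def _advance_threshold(x: float, u: float, dt: float, b: float, tau: float) -> float:
    """Exact update of x under constant u over dt (see module docstring)."""
    e = u - x
    ae = abs(e)
    if ae < 1e-15:  # numerically converged; avoids overflow of ae**(1-b)
        return u
    if b == 1.0:
        ae_new = ae * np.exp(-dt / tau)
    elif b > 1.0:
        ae_new = (ae ** (1.0 - b) + (b - 1.0) * dt / tau) ** (1.0 / (1.0 - b))
    else:  # b < 1: finite-time arrival at u
        base = ae ** (1.0 - b) - (1.0 - b) * dt / tau
        ae_new = base ** (1.0 / (1.0 - b)) if base > 0.0 else 0.0
    return u - np.copysign(ae_new, e)


def discharge_step(
    state: CSState, u_next: float, dt: float, params: CSParameters, substeps: int = 1
) -> CSState:
    """Advance the model by one sample.

    The previous input ``state.u`` is held (zero-order hold) while x is
    integrated over ``dt``; the new output is then evaluated against the new
    sample, so a step in u is reflected in y before x has moved -- the
    phasic burst at a load step.

    ``substeps`` subdivides the hold interval.  Because the update is the
    exact flow of the threshold ODE, subdivision leaves the result unchanged
    (the flow is a semigroup); the parameter exists so that integration
    convergence can be demonstrated rather than assumed.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    if not np.isfinite(u_next):
        raise ValueError("non-finite input sample (corrupt input)")
    if not np.isfinite(state.x):
        raise ValueError("non-finite threshold state")
    x_new = state.x
    for _ in range(substeps):
        x_new = _advance_threshold(x_new, state.u, dt / substeps, params.b, params.tau)
    return CSState(u=float(u_next), x=float(x_new), y=params.output(u_next, x_new))


def simulate_discharge(
    u_series,
    t,
    params: CSParameters,
    x0: Optional[float] = None,
    group: Optional[str] = None,
    substeps: int = 1,
) -> CSTrace:
    """Run the discharge model over a whole input series.

    ``x0`` defaults to ``u[0]`` (fully adapted start), which avoids a
    spurious startup transient.  Deterministic for fixed inputs.
    """
    u = np.asarray(u_series, dtype=float)
    t = np.asarray(t, dtype=float)
    if u.shape != t.shape:
        raise ValueError("u and t must have the same length")
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite input series (corrupt input)")
    n = len(t)
    x = np.empty(n)
    y = np.empty(n)
    x[0] = u[0] if x0 is None else float(x0)
    y[0] = params.output(u[0], x[0])
    if n > 1:
        dt = float(t[1] - t[0]) / substeps
        for i in range(1, n):
            xi = x[i - 1]
            for _ in range(substeps):
                xi = _advance_threshold(xi, u[i - 1], dt, params.b, params.tau)
            x[i] = xi
            y[i] = params.output(u[i], x[i])
    return CSTrace(t=t, u=u, x=x, y=y, group=group)


def steady_state_discharge(u: float, params: CSParameters) -> float:
    """Tonic discharge once x has fully adapted to u: max(0, c*u + d)."""
    if not np.isfinite(u):
        raise ValueError("non-finite input")
    return max(0.0, params.c * u + params.d)


def tonic_threshold(params: CSParameters) -> float:
    """Smallest constant input with nonzero adapted discharge, -d/c."""
    return -params.d / params.c


def group_bank(
    strains,
    params: Optional[Mapping[str, CSParameters]] = None,
    scales: Optional[Mapping[str, float]] = None,
    mapping: Optional[Mapping[str, str]] = None,
    x0: Optional[float] = None,
) -> Dict[str, CSTrace]:
    """Run all four CS groups on a strain record.

    ``strains`` is a :class:`cssim.synthetic_leg.StrainRecord` (anything with
    ``t`` and a ``channel(name)`` accessor works).  Each group's input is its
    rosette channel, signed, multiplied by that rosette's strain-to-u scale
    factor (see config).  Feeding the signed channel is what produces the
    release bursts: during stance a channel may sit below zero, the threshold
    adapts down to it, and the return to zero at unloading reads as a load
    increase for that group.
    """
    from .config import DEFAULT_CS_SCALES  # late import; config depends on us

    params = params or PRESETS
    scales = scales or DEFAULT_CS_SCALES
    mapping = mapping or GROUP_CHANNEL_MAP
    out: Dict[str, CSTrace] = {}
    for group, channel in mapping.items():
        try:
            raw = strains.channel(channel)
        except KeyError:
            raise KeyError(
                f"strain record lacks channel {channel!r} required by group {group}"
            ) from None
        rosette = channel.split("_", 1)[0]
        u = np.asarray(raw, dtype=float) * float(scales[rosette])
        out[group] = simulate_discharge(u, strains.t, params[group], x0=x0, group=group)
    return out
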