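"""Software stand-in for the physical robot leg: strain synthesis + sensors.

The robot measures strain with two gauge rosettes (proximal dorsal
trochanterofemur, proximal dorsal tibia).  Here a quasi-static beam model
replaces the hardware: at each instant the bending moment produced at each
gauge site by the foot contact force (vertical support of the carriage
weight plus belt friction, perturbations, ...) is resolved into the
segment-local dorso-ventral and anterior-posterior bending axes and
converted to surface strain with the hollow-square-section closed form.
Inertial strains are neglected -- the leg is dynamically scaled and moves
slowly, and on the hardware a freely moving (non-contacting) leg produces
essentially zero strain, which this model reproduces exactly.

Channel convention: each rosette yields an axial channel (strain along the
segment, positive for dorsally-directed bending load, i.e. compression of
the dorsal face under the sign convention used throughout) and a transverse
channel coupled as -nu times the axial bending strain (Poisson-style), so
the two channels of a rosette carry opposite signs and act as an
antagonistic sensor pair (groups 3/4 and 6B/6A).

The measured signal then passes through the emulated acquisition chain:
bridge voltage, x250 amplifier with slow offset drift, Gaussian electrical
noise, 12-bit ADC (clipping flagged), and a 13-sample moving median filter,
all at 60 samples/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .kinematics import FootPath, LegModel, default_leg, joint_frames, path_to_angles

__all__ = [
    "GRAVITY",
    "CHANNELS",
    "SegmentSection",
    "LoadState",
    "StrainRecord",
    "SensorChain",
    "LoadSchedule",
    "HalfSinePerturbation",
    "SlipEvent",
    "gauge_response_matrix",
    "strain_at_gauges",
    "sensor_chain",
    "simulate_static_loading",
    "simulate_stepping",
]

GRAVITY = 9.81  # m/s^2

#: Channel order used everywhere a (n, 4) strain array appears.
CHANNELS: Tuple[str, str, str, str] = (
    "tf_axial",
    "tf_transverse",
    "tib_axial",
    "tib_transverse",
)


@dataclass(frozen=True)
class SegmentSection:
    """Hollow square leg-segment cross-section (printed tube).

    outer and wall in mm; E in Pa (the printed polymer is ~1.4 GPa -- the
    absolute value only sets the strain scale, which the CS input scale
    factor absorbs).
    """

    outer: float = 10.0
    wall: float = 1.0
    E: float = 1.4e9

    def __post_init__(self) -> None:
        if not (self.outer > 0 and 0 < self.wall < self.outer / 2 and self.E > 0):
            raise ValueError("invalid section geometry")

    @property
    def area_moment(self) -> float:
        """Second moment of area, m^4 (hollow square closed form)."""
        o = self.outer * 1e-3
        i = (self.outer - 2 * self.wall) * 1e-3
        return (o**4 - i**4) / 12.0

    @property
    def half_depth(self) -> float:
        """Distance from neutral axis to the gauged surface, m."""
        return self.outer * 1e-3 / 2.0

    @property
    def strain_per_moment(self) -> float:
        """Surface strain per unit bending moment, 1/(N*m)."""
        return self.half_depth / (self.E * self.area_moment)


@dataclass
class LoadState:
    """Loading of the leg at one instant.

    When ``contact`` is False the distal end is free and, quasi-statically,
    every gauge strain is zero.  ``contact_force`` is the force the
    environment applies to the foot (N); ``carriage_mass`` (kg) adds its
    weight as a vertical (+z) support reaction at the foot;
    ``perturbation_force`` (N) is an additional vertical load.
    """

    contact: bool = True
    contact_force: np.ndarray = field(default_factory=lambda: np.zeros(3))
    carriage_mass: float = 0.0
    perturbation_force: float = 0.0

    def total_force(self) -> np.ndarray:
        f = np.asarray(self.contact_force, dtype=float).copy()
        f[2] += GRAVITY * self.carriage_mass + self.perturbation_force
        return f


@dataclass
class StrainRecord:
    """Multichannel strain time series at 60 samples/s with phase labels.

    ``channels`` holds the post-acquisition-chain strains (what the CS bank
    consumes); ``clean`` optionally holds the noiseless pre-chain strains
    (n, 4) for analysis, and ``saturated`` flags ADC clipping.
    """

    t: np.ndarray
    channels: Dict[str, np.ndarray]
    phase: np.ndarray
    clean: Optional[np.ndarray] = None
    saturated: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.phase = np.asarray(self.phase, dtype=bool)
        for name in CHANNELS:
            if name not in self.channels:
                raise KeyError(f"missing strain channel {name!r}")
        if len(self.phase) != len(self.t):
            raise ValueError("phase and t must have equal length")

    def channel(self, name: str) -> np.ndarray:
        return self.channels[name]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"t": self.t})
        df["phase"] = np.where(self.phase, "stance", "swing")
        for name in CHANNELS:
            df[name] = self.channels[name]
        return df


def _rosette_frames(angles, leg: LegModel, gauge_frac: float = 0.1):
    """Gauge site, long axis, and local AP/dorsal axes for both rosettes.

    Each rosette sits ``gauge_frac`` of the way along its segment from the
    proximal joint, on the dorsal face.  The local anterior-posterior axis
    is the segment frame's x axis; the dorsal normal completes the triad.
    """
    fr = joint_frames(angles, leg)
    sites = {}
    for name, (p_prox, p_dist, R_seg) in {
        "tf": (fr["p"][1], fr["p"][2], fr["R"][1]),
        "tib": (fr["p"][2], fr["foot"], fr["R"][2]),
    }.items():
        axis = p_dist - p_prox
        axis = axis / np.linalg.norm(axis)
        a_hat = R_seg @ np.array([1.0, 0.0, 0.0])  # local anterior-posterior
        d_hat = np.cross(a_hat, axis)  # local dorsal normal
        gauge = p_prox + gauge_frac * (p_dist - p_prox)
        sites[name] = {"gauge": gauge, "axis": axis, "a_hat": a_hat, "d_hat": d_hat}
    return sites, fr["foot"]


def gauge_response_matrix(
    angles,
    leg: Optional[LegModel] = None,
    section: Optional[SegmentSection] = None,
    gauge_frac: float = 0.1,
    poisson_coupling: float = 0.35,
    ap_weight: float = 0.0,
) -> np.ndarray:
    """(4, 3) linear map from foot force (N) to the four gauge strains.

    Row order follows :data:`CHANNELS`.  For each rosette the bending moment
    at the gauge site is M = r x F with r the lever arm to the foot (m);
    its component along the local AP axis bends the segment dorso-ventrally
    and produces the axial strain, the component along the dorsal normal is
    AP-plane bending.  axial = s_dv; transverse = -nu * s_dv + w_ap * s_ap.
    The map is exactly linear in the force, so strain superposition holds by
    construction.
    """
    leg = leg or default_leg()
    section = section or SegmentSection()
    sites, foot = _rosette_frames(angles, leg, gauge_frac)
    k = section.strain_per_moment
    W = np.empty((4, 3))
    for row, name in ((0, "tf"), (2, "tib")):
        s = sites[name]
        r_m = (foot - s["gauge"]) * 1e-3  # mm -> m
        w_dv = k * np.cross(s["a_hat"], r_m)  # strain/N from DV bending
        w_ap = k * np.cross(s["d_hat"], r_m)  # strain/N from AP bending
        W[row] = w_dv
        W[row + 1] = -poisson_coupling * w_dv + ap_weight * w_ap
    return W


def strain_at_gauges(
    angles,
    load: LoadState,
    leg: Optional[LegModel] = None,
    section: Optional[SegmentSection] = None,
    **kwargs,
) -> np.ndarray:
    """Quasi-static strain (4,) at the gauges for one configuration and load.

    Zero whenever the distal end is free -- the dynamically scaled leg
    develops no appreciable inertial strain.
    """
    if not load.contact:
        return np.zeros(4)
    W = gauge_response_matrix(angles, leg, section, **kwargs)
    return W @ load.total_force()


@dataclass(frozen=True)
class SensorChain:
    """Amplifier -> ADC -> median filter emulation with published defaults.

    bridge_sens converts strain to bridge voltage (V/strain); the amplifier
    multiplies by ``gain`` and centers the signal at vref/2.  Offset drift
    (slow sinusoid, trimpot/temperature effects) and Gaussian electrical
    noise are added in volts, the result is clipped to [0, vref], quantized
    to 2**adc_bits levels, and median-filtered over ``window`` samples.
    """

    gain: float = 250.0
    adc_bits: int = 12
    vref: float = 3.3
    fs: float = 60.0
    window: int = 13
    bridge_sens: float = 0.2
    noise_sd_counts: float = 2.0
    drift_amp_counts: float = 5.0
    drift_period: float = 60.0

    @property
    def levels(self) -> int:
        return 2**self.adc_bits

    @property
    def lsb(self) -> float:
        """Quantization step in volts: full scale over 2**bits."""
        return self.vref / self.levels

    @property
    def volts_per_strain(self) -> float:
        return self.gain * self.bridge_sens

    def apply(self, raw: np.ndarray, t: np.ndarray, rng: Optional[np.random.Generator] = None):
        """Run strain series (n,) or (n, k) through the chain.

        Returns (codes, strain, saturated): filtered integer ADC codes, the
        strain recovered from them, and a clipping flag per sample.
        Deterministic for a given ``rng`` state; with ``rng=None`` no noise
        or drift is added.
        """
        raw = np.asarray(raw, dtype=float)
        squeeze = raw.ndim == 1
        sig = raw[:, None] if squeeze else raw
        v = self.vref / 2.0 + self.volts_per_strain * sig
        if rng is not None:
            phase = rng.uniform(0.0, 2.0 * np.pi, size=sig.shape[1])
            drift = self.drift_amp_counts * self.lsb * np.sin(
                2.0 * np.pi * np.asarray(t)[:, None] / self.drift_period + phase
            )
            noise = rng.normal(0.0, self.noise_sd_counts * self.lsb, size=sig.shape)
            v = v + drift + noise
        saturated = (v < 0.0) | (v > self.vref)
        v = np.clip(v, 0.0, self.vref)
        codes = np.rint(v / self.lsb)
        codes = np.clip(codes, 0, self.levels - 1).astype(np.int64)
        filt = median_filter(codes, size=(self.window, 1), mode="nearest")
        strain = (filt * self.lsb - self.vref / 2.0) / self.volts_per_strain
        if squeeze:
            return filt[:, 0], strain[:, 0], saturated[:, 0]
        return filt, strain, saturated


def sensor_chain(
    raw,
    gain: float = 250.0,
    adc_bits: int = 12,
    vref: float = 3.3,
    noise_sd: Optional[float] = None,
    fs: float = 60.0,
    window: int = 13,
    seed: Optional[int] = None,
    **kwargs,
) -> np.ndarray:
    """Functional form of :class:`SensorChain`: returns filtered ADC codes.

    ``noise_sd`` is in volts (default: 2 ADC counts).  Pass ``seed`` for
    reproducible noise; without it the chain is noiseless.
    """
    if not gain > 0:
        raise ValueError("gain must be positive")
    if adc_bits < 1:
        raise ValueError("adc_bits must be >= 1")
    lsb = vref / 2**adc_bits
    chain = SensorChain(
        gain=gain,
        adc_bits=adc_bits,
        vref=vref,
        fs=fs,
        window=window,
        noise_sd_counts=(noise_sd / lsb) if noise_sd is not None else 2.0,
        **kwargs,
    )
    raw = np.asarray(raw, dtype=float)
    t = np.arange(raw.shape[0]) / fs
    rng = np.random.default_rng(seed) if seed is not None else None
    codes, _, _ = chain.apply(raw, t, rng)
    return codes


@dataclass(frozen=True)
class HalfSinePerturbation:
    """Transient vertical load: half sine of ``amplitude`` N starting
    ``onset`` s after stance onset, lasting ``duration`` s."""

    onset: float = 1.25
    duration: float = 0.5
    amplitude: float = 5.0

    def force(self, t_stance: float) -> float:
        s = t_stance - self.onset
        if 0.0 <= s <= self.duration:
            return self.amplitude * float(np.sin(np.pi * s / self.duration))
        return 0.0


@dataclass(frozen=True)
class SlipEvent:
    """Mid-stance foot slip: the tibial bending moment collapses (direction
    +1) or transiently increases (direction -1) over the slip window, while
    the trochanterofemoral moment rises; edges are smoothed over ``edge`` s.
    Purely phenomenological -- the hardware produces this through friction
    breakdown, which has no printed model."""

    onset: float = 0.9
    duration: float = 0.4
    direction: int = 1
    tf_gain: float = 0.5
    edge: float = 0.05

    def profile(self, t_stance: float) -> float:
        s = t_stance - self.onset
        if s < 0.0 or s > self.duration:
            return 0.0
        rise = min(1.0, s / self.edge)
        fall = min(1.0, (self.duration - s) / self.edge)
        return min(rise, fall)


@dataclass
class LoadSchedule:
    """Loading protocol for treadmill stepping.

    The carriage (body) weight plus any added mass is supported by the leg
    during stance; load transfer at touchdown and liftoff happens at a fixed
    force rate ``ramp_rate`` (N/s) -- set by contact mechanics, not by the
    carried mass, which is why the touchdown strain *rate* is
    load-insensitive while mid-stance strain amplitude scales with load.
    Belt friction is kinetic, mu * normal force, opposing the leg's push.
    """

    carriage_mass: float = 0.8
    added_mass: float = 0.0
    ramp_rate: float = 100.0
    mu: float = 0.4
    perturbation: Optional[HalfSinePerturbation] = None
    slip: Optional[SlipEvent] = None

    def supported_weight(self) -> float:
        return GRAVITY * (self.carriage_mass + self.added_mass)


def simulate_static_loading(
    angles,
    force_series: np.ndarray,
    contact: np.ndarray,
    leg: Optional[LegModel] = None,
    section: Optional[SegmentSection] = None,
    chain: Optional[SensorChain] = None,
    seed: Optional[int] = None,
    fs: float = 60.0,
) -> StrainRecord:
    """Strain record for a fixed posture under a scheduled foot force.

    Used by the ramp-hold-release and asterisk protocols: the leg holds one
    configuration while the (possibly zero) contact force cycles.  Samples
    with ``contact`` False yield exactly zero pre-chain strain.
    """
    leg = leg or default_leg()
    section = section or SegmentSection()
    chain = chain or SensorChain(fs=fs)
    force_series = np.asarray(force_series, dtype=float).reshape(-1, 3)
    contact = np.asarray(contact, dtype=bool)
    n = len(force_series)
    t = np.arange(n) / chain.fs
    W = gauge_response_matrix(angles, leg, section)
    clean = force_series @ W.T
    clean[~contact] = 0.0
    rng = np.random.default_rng(seed) if seed is not None else None
    _, strain, sat = chain.apply(clean, t, rng)
    channels = {name: strain[:, i] for i, name in enumerate(CHANNELS)}
    return StrainRecord(t=t, channels=channels, phase=contact, clean=clean, saturated=sat)


def simulate_stepping(
    path: FootPath,
    schedule: Optional[LoadSchedule] = None,
    leg: Optional[LegModel] = None,
    section: Optional[SegmentSection] = None,
    seed: Optional[int] = 0,
    n_steps: int = 1,
    chain: Optional[SensorChain] = None,
    angles: Optional[np.ndarray] = None,
) -> StrainRecord:
    """Simulate ``n_steps`` treadmill steps and return the strain record.

    Per sample: during stance the foot is constrained to the treadmill and
    carries the vertical reaction (carriage weight, ramped at touchdown and
    liftoff, plus any perturbation) and a friction force consistent with the
    belt motion; during swing the foot is free and strains are zero before
    the acquisition chain adds its noise.  The per-period geometry is
    computed once and reused, so the deterministic part of every step is
    identical.  ``angles`` may carry a precomputed inverse-kinematics
    solution for the path (one period).
    """
    schedule = schedule or LoadSchedule()
    leg = leg or default_leg()
    section = section or SegmentSection()
    chain = chain or SensorChain(fs=path.fs)
    if angles is None:
        angles = path_to_angles(path, leg)
    n_per = len(path.t)
    Ts = path.duty * path.step_period

    # Per-period strain/force maps (geometry only).
    W = np.stack([gauge_response_matrix(angles[i], leg, section) for i in range(n_per)])

    n = n_per * n_steps
    t = np.arange(n) / path.fs
    phase = np.tile(path.phase, n_steps)
    clean = np.zeros((n, 4))
    weight = schedule.supported_weight()
    for i in range(n):
        j = i % n_per
        if not path.phase[j]:
            continue
        ts = path.t[j]  # time since stance onset (stance starts each period)
        target = weight
        if schedule.perturbation is not None:
            target += schedule.perturbation.force(ts)
        N = min(target, schedule.ramp_rate * ts, schedule.ramp_rate * (Ts - ts))
        N = max(0.0, N)
        F = np.array([-schedule.mu * N, 0.0, N])
        eps = W[j] @ F
        if schedule.slip is not None:
            p = schedule.slip.profile(ts)
            if p > 0.0:
                tib_mult = 1.0 - p if schedule.slip.direction >= 0 else 1.0 + p
                eps[2:] *= tib_mult
                eps[:2] *= 1.0 + schedule.slip.tf_gain * p
        clean[i] = eps

    rng = np.random.default_rng(seed) if seed is not None else None
    _, strain, sat = chain.apply(clean, t, rng)
    channels = {name: strain[:, i] for i, name in enumerate(CHANNELS)}
    return StrainRecord(t=t, channels=channels, phase=phase, clean=clean, saturated=sat)
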