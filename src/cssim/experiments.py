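"""Declarative runners for the five load-sensing protocols.

Each protocol drives the full pipeline -- strain synthesis, acquisition
chain, CS discharge bank -- and returns every intermediate series plus a
per-protocol summary table:

* ``ramp_hold_release_fixed`` / ``ramp_hold_release_free``: trapezoidal
  bending load on the trochanterofemur with the distal end clamped or free;
  the classic fixture for phasic discharge and for the no-inertial-strain
  control.
* ``asterisk``: the distal end is held while the load direction cycles
  through 12 directions 30 degrees apart (dorsal -> anterior -> ventral ->
  posterior), mapping the directional tuning of the two rosette channels.
* ``stepping_load``: treadmill stepping while the leg supports the carriage
  weight plus 0/500/1000 g.
* ``transient_load``: stepping with a half-sine downward pull on the
  carriage during stance.
* ``slip``: stepping with a mid-stance foot slip that collapses the tibial
  bending moment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import cs_model
from .cs_model import CSParameters, CSTrace
from .kinematics import LegModel, default_leg, generate_footpath, inverse_kinematics, path_to_angles
from .synthetic_leg import (
    CHANNELS,
    HalfSinePerturbation,
    LoadSchedule,
    SegmentSection,
    SensorChain,
    SlipEvent,
    StrainRecord,
    _rosette_frames,
    simulate_static_loading,
    simulate_stepping,
)

__all__ = [
    "PROTOCOLS",
    "ExperimentSpec",
    "ExperimentResult",
    "ProtocolMismatchError",
    "run_experiment",
    "asterisk_polar_summary",
    "stance_event_detector",
]

PROTOCOLS = (
    "ramp_hold_release_fixed",
    "ramp_hold_release_free",
    "asterisk",
    "stepping_load",
    "transient_load",
    "slip",
)

_DEFAULTS: Dict[str, Dict[str, float]] = {
    "ramp_hold_release_fixed": dict(ramp=0.5, hold=2.0, release=0.5, pad=1.0, force=6.0),
    "ramp_hold_release_free": dict(ramp=0.5, hold=2.0, release=0.5, pad=1.0, force=6.0),
    "asterisk": dict(force=6.0, dwell=1.0, transition=0.25, center_dwell=0.5),
    "stepping_load": dict(added_mass=0.0, n_steps=20, step_period=4.0,
                          treadmill_speed=40.0, duty=0.5),
    "transient_load": dict(added_mass=0.0, n_steps=20, step_period=4.0,
                           treadmill_speed=40.0, duty=0.5,
                           perturb_onset=1.25, perturb_duration=0.5, perturb_amplitude=5.0),
    "slip": dict(added_mass=0.0, n_steps=20, step_period=4.0,
                 treadmill_speed=40.0, duty=0.5,
                 slip_onset=0.9, slip_duration=0.4, slip_direction=1),
}


class ProtocolMismatchError(ValueError):
    """A summary was requested for a result of the wrong protocol."""


@dataclass(frozen=True)
class ExperimentSpec:
    """Declarative description of one protocol run.

    ``parameters`` may override the protocol's defaults; unknown keys are
    rejected with a list of the offending fields.
    """

    name: str
    parameters: Dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.name!r}; expected one of {PROTOCOLS}")
        bad = sorted(set(self.parameters) - set(_DEFAULTS[self.name]))
        if bad:
            raise ValueError(f"invalid parameters for {self.name!r}: {bad}")

    def resolved(self) -> Dict[str, float]:
        out = dict(_DEFAULTS[self.name])
        out.update(self.parameters)
        return out


@dataclass
class ExperimentResult:
    spec: ExperimentSpec
    strain: StrainRecord
    discharges: Dict[str, CSTrace]
    events: pd.DataFrame
    summaries: pd.DataFrame


def _trapezoid(fs: float, pad: float, ramp: float, hold: float, release: float):
    """Unit trapezoid with flat pads on both sides, sampled at fs."""
    seg = lambda dur: int(round(dur * fs))
    parts = [
        np.zeros(seg(pad)),
        np.linspace(0.0, 1.0, seg(ramp), endpoint=False),
        np.ones(seg(hold)),
        np.linspace(1.0, 0.0, seg(release), endpoint=False),
        np.zeros(seg(pad)),
    ]
    return np.concatenate(parts)


def _stance_posture(leg: LegModel):
    from .kinematics import GROUND_Z, STANCE_GUESS, STANCE_Y

    return inverse_kinematics(
        np.array([0.0, STANCE_Y, GROUND_Z]), leg, guess=STANCE_GUESS
    ).as_array()


def _bank(strain, cs_params, scales):
    return cs_model.group_bank(strain, params=cs_params, scales=scales)


def run_experiment(
    spec: ExperimentSpec,
    leg: Optional[LegModel] = None,
    section: Optional[SegmentSection] = None,
    cs_params: Optional[Dict[str, CSParameters]] = None,
    scales: Optional[Dict[str, float]] = None,
    chain: Optional[SensorChain] = None,
) -> ExperimentResult:
    """Execute a protocol end to end, deterministically under ``spec.seed``."""
    leg = leg or default_leg()
    section = section or SegmentSection()
    chain = chain or SensorChain()
    p = spec.resolved()
    fs = chain.fs

    if spec.name.startswith("ramp_hold_release"):
        posture = _stance_posture(leg)
        env = _trapezoid(fs, p["pad"], p["ramp"], p["hold"], p["release"])
        sites, _ = _rosette_frames(posture, leg)
        force = np.outer(env * p["force"], sites["tf"]["d_hat"])  # dorsal load
        fixed = spec.name.endswith("fixed")
        contact = np.full(len(env), fixed)
        strain = simulate_static_loading(
            posture, force, contact, leg, section, chain, seed=spec.seed, fs=fs
        )
        t0 = p["pad"]
        events = pd.DataFrame(
            [
                {"label": "ramp", "t0": t0, "t1": t0 + p["ramp"]},
                {"label": "hold", "t0": t0 + p["ramp"], "t1": t0 + p["ramp"] + p["hold"]},
                {"label": "release", "t0": t0 + p["ramp"] + p["hold"],
                 "t1": t0 + p["ramp"] + p["hold"] + p["release"]},
            ]
        )
        discharges = _bank(strain, cs_params, scales)
        summaries = pd.DataFrame(
            {"group": list(discharges), "peak_discharge": [d.y.max() for d in discharges.values()]}
        )
        return ExperimentResult(spec, strain, discharges, events, summaries)

    if spec.name == "asterisk":
        posture = _stance_posture(leg)
        sites, _ = _rosette_frames(posture, leg)
        d_hat, a_hat = sites["tf"]["d_hat"], sites["tf"]["a_hat"]
        n_tr = int(round(p["transition"] * fs))
        n_dw = int(round(p["dwell"] * fs))
        n_cd = int(round(p["center_dwell"] * fs))
        angles_deg = np.arange(12) * 30.0
        blocks, rows = [], []
        t_cursor = 0.0
        for ang in angles_deg:
            phi = np.radians(ang)
            direction = np.cos(phi) * d_hat + np.sin(phi) * a_hat
            env = np.concatenate(
                [
                    np.linspace(0.0, 1.0, n_tr, endpoint=False),
                    np.ones(n_dw),
                    np.linspace(1.0, 0.0, n_tr, endpoint=False),
                    np.zeros(n_cd),
                ]
            )
            blocks.append(np.outer(env * p["force"], direction))
            hold0 = t_cursor + p["transition"]
            rows.append({"label": f"hold_{ang:g}", "t0": hold0, "t1": hold0 + p["dwell"],
                         "direction_deg": ang})
            t_cursor += p["transition"] * 2 + p["dwell"] + p["center_dwell"]
        force = np.vstack(blocks)
        contact = np.ones(len(force), dtype=bool)
        strain = simulate_static_loading(
            posture, force, contact, leg, section, chain, seed=spec.seed, fs=fs
        )
        events = pd.DataFrame(rows)
        discharges = _bank(strain, cs_params, scales)
        result = ExperimentResult(spec, strain, discharges, events, pd.DataFrame())
        result.summaries = asterisk_polar_summary(result)
        return result

    # treadmill stepping family
    path = generate_footpath(
        step_period=p["step_period"],
        treadmill_speed=p["treadmill_speed"],
        duty=p["duty"],
        leg=leg,
        fs=fs,
    )
    schedule = LoadSchedule(added_mass=p["added_mass"])
    rows = []
    if spec.name == "transient_load":
        schedule.perturbation = HalfSinePerturbation(
            onset=p["perturb_onset"], duration=p["perturb_duration"],
            amplitude=p["perturb_amplitude"],
        )
    if spec.name == "slip":
        schedule.slip = SlipEvent(
            onset=p["slip_onset"], duration=p["slip_duration"],
            direction=int(p["slip_direction"]),
        )
    n_steps = int(p["n_steps"])
    angles = path_to_angles(path, leg)
    strain = simulate_stepping(
        path, schedule, leg, section, seed=spec.seed, n_steps=n_steps,
        chain=chain, angles=angles,
    )
    Ts = p["duty"] * p["step_period"]
    for k in range(n_steps):
        base = k * p["step_period"]
        rows.append({"label": "stance", "t0": base, "t1": base + Ts})
        if schedule.perturbation is not None:
            rows.append({"label": "perturbation", "t0": base + p["perturb_onset"],
                         "t1": base + p["perturb_onset"] + p["perturb_duration"]})
        if schedule.slip is not None:
            rows.append({"label": "slip", "t0": base + p["slip_onset"],
                         "t1": base + p["slip_onset"] + p["slip_duration"]})
    events = pd.DataFrame(rows)
    discharges = _bank(strain, cs_params, scales)
    summaries = pd.DataFrame(
        {
            "group": list(discharges),
            "channel": [cs_model.GROUP_CHANNEL_MAP[g] for g in discharges],
            "peak_discharge": [d.y.max() for d in discharges.values()],
            "peak_strain": [np.max(np.abs(strain.clean[:, CHANNELS.index(
                cs_model.GROUP_CHANNEL_MAP[g])])) for g in discharges],
        }
    )
    return ExperimentResult(spec, strain, discharges, events, summaries)


def asterisk_polar_summary(result: ExperimentResult) -> pd.DataFrame:
    """Mean strain per channel over each direction's hold window.

    One row per direction (12 rows, 30 degrees apart); the mean is taken
    over the central 60% of each hold, excluding the move-and-return
    transition samples.
    """
    if result.spec.name != "asterisk":
        raise ProtocolMismatchError(
            f"asterisk summary requested for {result.spec.name!r} result"
        )
    rows = []
    t = result.strain.t
    for _, ev in result.events.iterrows():
        span = ev.t1 - ev.t0
        lo, hi = ev.t0 + 0.2 * span, ev.t1 - 0.2 * span
        sel = (t >= lo) & (t <= hi)
        row = {"direction_deg": ev.direction_deg}
        for name in CHANNELS:
            row[name] = float(np.mean(result.strain.channel(name)[sel]))
        rows.append(row)
    return pd.DataFrame(rows)


def stance_event_detector(
    discharges: Dict[str, CSTrace],
    threshold: Optional[float] = None,
    phase: Optional[np.ndarray] = None,
    onset_group: str = "3",
    offset_group: str = "4",
) -> pd.DataFrame:
    """Detect stance onsets and offsets from the CS discharge bank.

    Stance onset is an upward threshold crossing of the trochanterofemoral
    axial group (3); stance offset an upward crossing of its antagonist
    (4), whose release burst marks unloading.  ``threshold`` defaults to
    10% of each group's peak discharge over the record.  With ground-truth
    ``phase`` labels, each true phase transition is matched to the nearest
    detection of the right kind and the timing error reported (one row per
    transition, ``t`` NaN when nothing was detected); without them the raw
    detections are returned.  No events is a valid, empty result.
    """
    rows = []
    detections = {}
    for kind, group in (("onset", onset_group), ("offset", offset_group)):
        tr = discharges[group]
        thr = threshold if threshold is not None else 0.1 * tr.y.max()
        if thr <= 0:
            detections[kind] = np.array([])
            continue
        above = tr.y >= thr
        crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
        if above[0]:
            crossings = np.insert(crossings, 0, 0)
        detections[kind] = tr.t[crossings]

    if phase is None:
        for kind, ts in detections.items():
            rows.extend({"kind": kind, "t": t, "t_truth": np.nan, "error": np.nan} for t in ts)
        return pd.DataFrame(rows, columns=["kind", "t", "t_truth", "error"])

    phase = np.asarray(phase, dtype=bool)
    some = next(iter(discharges.values()))
    t_axis = some.t
    on_idx = np.flatnonzero(np.diff(phase.astype(int)) == 1) + 1
    if phase[0]:
        on_idx = np.insert(on_idx, 0, 0)
    off_idx = np.flatnonzero(np.diff(phase.astype(int)) == -1) + 1
    truth = {"onset": t_axis[on_idx], "offset": t_axis[off_idx]}
    for kind in ("onset", "offset"):
        det = detections[kind]
        for tt in truth[kind]:
            if len(det) == 0:
                rows.append({"kind": kind, "t": np.nan, "t_truth": tt, "error": np.nan})
            else:
                j = int(np.argmin(np.abs(det - tt)))
                rows.append(
                    {"kind": kind, "t": det[j], "t_truth": tt, "error": abs(det[j] - tt)}
                )
    return pd.DataFrame(rows, columns=["kind", "t", "t_truth", "error"])
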