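"""Delimited-text I/O for traces, strain records and angle/path series."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cs_model import CSTrace
from .synthetic_leg import CHANNELS, StrainRecord

__all__ = [
    "read_input_trace",
    "write_trace",
    "read_trace",
    "write_strain_record",
    "read_strain_record",
    "write_angles",
    "write_footpath",
]


def read_input_trace(path):
    """Read a `t,u` CSV; returns (t, u) arrays."""
    df = pd.read_csv(path)
    if not {"t", "u"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns t,u")
    return df["t"].to_numpy(float), df["u"].to_numpy(float)


def write_trace(trace: CSTrace, path) -> None:
    trace.to_frame().to_csv(path, index=False)


def read_trace(path) -> CSTrace:
    df = pd.read_csv(path)
    return CSTrace(t=df["t"].to_numpy(), u=df["u"].to_numpy(),
                   x=df["x"].to_numpy(), y=df["y"].to_numpy())


def write_strain_record(record: StrainRecord, path) -> None:
    record.to_frame().to_csv(path, index=False)


def read_strain_record(path) -> StrainRecord:
    df = pd.read_csv(path)
    channels = {name: df[name].to_numpy(float) for name in CHANNELS}
    return StrainRecord(
        t=df["t"].to_numpy(float),
        channels=channels,
        phase=(df["phase"] == "stance").to_numpy(),
    )


def write_angles(t, angles, path) -> None:
    pd.DataFrame(
        {"t": t, "theta1": angles[:, 0], "theta2": angles[:, 1], "theta3": angles[:, 2]}
    ).to_csv(path, index=False)


def write_footpath(path_obj, path) -> None:
    pts = path_obj.points
    pd.DataFrame(
        {
            "t": path_obj.t,
            "x": pts[:, 0],
            "y": pts[:, 1],
            "z": pts[:, 2],
            "phase": np.where(path_obj.phase, "stance", "swing"),
        }
    ).to_csv(path, index=False)
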