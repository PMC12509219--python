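"""Readers and writers for recordings, traces, calibrations and events.

Two interchangeable on-disk forms are supported for time series:

- HDF5 containers (datasets ``time``, ``vdc``, ``vif1..vif4``; the
  instrument config snapshot as a JSON attribute), and
- plain CSV with a header row, comma separator, '.' decimal, UTF-8, and
  units embedded in column names (``time_s``, ``vdc_V``, ``vif1_V``..).

Time is always seconds from recording start; event files share that origin.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .estimation import LifetimeTrace
from .instrument import ChannelState, DarkRecording, InstrumentConfig, PhaseRampRecording, RawRecording
from .analysis import EventSet
from .phasor import ModulationContext

__all__ = [
    "config_to_dict",
    "config_from_dict",
    "write_recording",
    "read_recording",
    "write_trace",
    "read_trace",
    "write_phase_ramp",
    "read_phase_ramp",
    "write_dark",
    "read_dark",
    "read_events",
    "write_events",
]

_REC_COLUMNS = ["time_s", "vdc_V", "vif1_V", "vif2_V", "vif3_V", "vif4_V"]


def config_to_dict(config: InstrumentConfig) -> dict:
    d = dataclasses.asdict(config)
    d["ctx"] = {"modulation_frequency": config.ctx.modulation_frequency}
    return d


def config_from_dict(d: dict) -> InstrumentConfig:
    d = dict(d)
    d["ctx"] = ModulationContext(**d["ctx"])
    d["channels"] = tuple(
        ChannelState(
            nominal_shift=ch["nominal_shift"],
            channel_offset=ch["channel_offset"],
            shifter_curve=tuple(ch["shifter_curve"]),
        )
        for ch in d["channels"]
    )
    if d.get("bias_voltages") is not None:
        d["bias_voltages"] = tuple(d["bias_voltages"])
    return InstrumentConfig(**d)


def write_recording(rec: RawRecording, path) -> None:
    """Write a raw recording; format chosen from the file suffix (.h5/.csv)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            fh.create_dataset("time", data=rec.time)
            fh.create_dataset("vdc", data=rec.vdc)
            for i in range(4):
                fh.create_dataset(f"vif{i + 1}", data=rec.vif[i])
            fh.attrs["config"] = json.dumps(config_to_dict(rec.config_snapshot))
    elif path.suffix == ".csv":
        df = pd.DataFrame(
            dict(
                zip(
                    _REC_COLUMNS,
                    [rec.time, rec.vdc, rec.vif[0], rec.vif[1], rec.vif[2], rec.vif[3]],
                )
            )
        )
        df.to_csv(path, index=False)
        path.with_suffix(".config.json").write_text(
            json.dumps(config_to_dict(rec.config_snapshot), indent=2)
        )
    else:
        raise ValueError(f"unsupported recording format: {path.suffix}")


def read_recording(path) -> RawRecording:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            for name in ("time", "vdc", "vif1", "vif2", "vif3", "vif4"):
                if name not in fh:
                    raise ValueError(f"missing channel '{name}' in {path}")
            time = fh["time"][:]
            vdc = fh["vdc"][:]
            vif = np.stack([fh[f"vif{i + 1}"][:] for i in range(4)])
            config = config_from_dict(json.loads(fh.attrs["config"]))
    elif path.suffix == ".csv":
        df = pd.read_csv(path, float_precision="round_trip")
        missing = [c for c in _REC_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing channel column(s) {missing} in {path}")
        time = df["time_s"].to_numpy()
        vdc = df["vdc_V"].to_numpy()
        vif = np.stack([df[f"vif{i + 1}_V"].to_numpy() for i in range(4)])
        sidecar = path.with_suffix(".config.json")
        if sidecar.exists():
            config = config_from_dict(json.loads(sidecar.read_text()))
        else:
            fs = float(1.0 / np.median(np.diff(time)))
            config = InstrumentConfig(sample_rate=fs, if_bandwidth=fs / 2)
    else:
        raise ValueError(f"unsupported recording format: {path.suffix}")
    return RawRecording(time=time, vdc=vdc, vif=vif, config_snapshot=config)


_TRACE_COLUMNS = ["time_s", "lifetime_ns", "intensity_V", "g", "s"]


def write_trace(trace: LifetimeTrace, path) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            for name, arr in zip(
                ("time", "lifetime_ns", "intensity", "g", "s"),
                (trace.time, trace.lifetime_ns, trace.intensity, trace.g, trace.s),
            ):
                fh.create_dataset(name, data=arr)
            fh.attrs["rate"] = trace.rate
    elif path.suffix == ".csv":
        pd.DataFrame(
            dict(
                zip(
                    _TRACE_COLUMNS,
                    [trace.time, trace.lifetime_ns, trace.intensity, trace.g, trace.s],
                )
            )
        ).to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported trace format: {path.suffix}")


def read_trace(path) -> LifetimeTrace:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            return LifetimeTrace(
                time=fh["time"][:],
                lifetime_ns=fh["lifetime_ns"][:],
                intensity=fh["intensity"][:],
                g=fh["g"][:],
                s=fh["s"][:],
                rate=float(fh.attrs["rate"]),
            )
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing trace column(s) {missing} in {path}")
    time = df["time_s"].to_numpy()
    rate = float(1.0 / np.median(np.diff(time))) if len(time) > 1 else 1.0
    return LifetimeTrace(
        time=time,
        lifetime_ns=df["lifetime_ns"].to_numpy(),
        intensity=df["intensity_V"].to_numpy(),
        g=df["g"].to_numpy(),
        s=df["s"].to_numpy(),
        rate=rate,
    )


def write_phase_ramp(ramp: PhaseRampRecording, path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "bias_V": ramp.bias_voltage,
            "vif1_V": ramp.vif[0],
            "vif2_V": ramp.vif[1],
            "vif3_V": ramp.vif[2],
            "vif4_V": ramp.vif[3],
        }
    )
    df.to_csv(path, index=False)
    path.with_suffix(".meta.json").write_text(
        json.dumps(
            {"vdc": ramp.vdc, "standard_lifetime_ns": ramp.standard_lifetime_ns}
        )
    )


def read_phase_ramp(path) -> PhaseRampRecording:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    return PhaseRampRecording(
        bias_voltage=df["bias_V"].to_numpy(),
        vif=np.stack([df[f"vif{i + 1}_V"].to_numpy() for i in range(4)]),
        vdc=meta["vdc"],
        standard_lifetime_ns=meta["standard_lifetime_ns"],
    )


def write_dark(dark: DarkRecording, path) -> None:
    pd.DataFrame(
        {
            "vdc_V": dark.vdc,
            "vif1_V": dark.vif[0],
            "vif2_V": dark.vif[1],
            "vif3_V": dark.vif[2],
            "vif4_V": dark.vif[3],
        }
    ).to_csv(path, index=False)


def read_dark(path) -> DarkRecording:
    df = pd.read_csv(path, float_precision="round_trip")
    return DarkRecording(
        vdc=df["vdc_V"].to_numpy(),
        vif=np.stack([df[f"vif{i + 1}_V"].to_numpy() for i in range(4)]),
    )


def write_events(events: EventSet, path) -> None:
    pd.DataFrame(
        {
            "time_s": events.event_times,
            "label": events.labels or [""] * len(events.event_times),
        }
    ).to_csv(path, index=False)


def read_events(path) -> EventSet:
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise ValueError(f"events file {path} lacks a time_s column")
    labels = (
        tuple(str(x) for x in df["label"]) if "label" in df.columns else ()
    )
    return EventSet(event_times=df["time_s"].to_numpy(), labels=labels)
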