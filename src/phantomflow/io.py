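"""Readers, writers, run configuration and manifests.

Two interchange layouts exist for velocity fields:

* long-format delimited text with header ``frame,t,x,y,ux,uy,tq,valid``
  (comma separated, '.' decimal, UTF-8);
* a single HDF5 container with named datasets ``x, y, t, ux, uy, tq, valid``
  and a JSON metadata attribute (units and the coordinate-convention string).

Pressures cross all text interfaces in mmHg; arrays are SI in memory.
"""
from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .errors import DataError, ParameterError
from .fields import ScanGrid, VelocityField2D
from .pulses import PressureTrace
from .synthetic import PulseWaveform
from .units import MMHG_PA, pa_to_mmhg

__all__ = [
    "write_velocity_field",
    "read_velocity_field",
    "write_waveform",
    "read_waveform",
    "write_phantom_result",
    "write_trace",
    "read_trace",
    "RunConfig",
    "RunLog",
]

CONVENTION = "x rightward, y upward, arrays (frame, y, x); SI units"


def _meta_json(field_: VelocityField2D) -> str:
    return json.dumps(
        {"units": {"x": "m", "y": "m", "t": "s", "ux": "m/s", "uy": "m/s"}, "convention": CONVENTION, **field_.meta},
        sort_keys=True,
        default=str,
    )


def write_velocity_field(field_: VelocityField2D, path, fmt: str | None = None) -> None:
    """Write a field as long-format CSV (``.csv``) or HDF5 (``.h5``/``.hdf5``)."""
    path = Path(path)
    fmt = fmt or ("csv" if path.suffix.lower() == ".csv" else "hdf5")
    g = field_.grid
    if fmt == "csv":
        nt, ny, nx = g.shape
        frame, iy, ix = np.meshgrid(np.arange(nt), np.arange(ny), np.arange(nx), indexing="ij")
        df = pd.DataFrame(
            {
                "frame": frame.ravel(),
                "t": g.t[frame.ravel()],
                "x": g.x[ix.ravel()],
                "y": g.y[iy.ravel()],
                "ux": field_.ux.ravel(),
                "uy": field_.uy.ravel(),
                "tq": field_.tq.ravel(),
                "valid": field_.valid.ravel().astype(int),
            }
        )
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# phantomflow velocity field; metadata: {_meta_json(field_)}\n")
            df.to_csv(fh, index=False)
    elif fmt == "hdf5":
        with h5py.File(path, "w") as h5:
            for name, arr in (
                ("x", g.x),
                ("y", g.y),
                ("t", g.t),
                ("ux", field_.ux),
                ("uy", field_.uy),
                ("tq", field_.tq),
                ("valid", field_.valid),
            ):
                h5.create_dataset(name, data=arr)
            h5.attrs["metadata"] = _meta_json(field_)
    else:
        raise ParameterError(f"unknown velocity-field format {fmt!r}")


def read_velocity_field(path, fmt: str | None = None) -> VelocityField2D:
    """Read either velocity-field layout, validating the container invariants."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    fmt = fmt or ("csv" if path.suffix.lower() == ".csv" else "hdf5")
    if fmt == "csv":
        meta = {}
        with open(path, encoding="utf-8") as fh:
            first = fh.readline()
            if first.startswith("#"):
                marker = "metadata: "
                if marker in first:
                    meta = json.loads(first.split(marker, 1)[1])
                df = pd.read_csv(fh, float_precision="round_trip")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, float_precision="round_trip")
        required = {"frame", "t", "x", "y", "ux", "uy", "tq", "valid"}
        if not required.issubset(df.columns):
            raise DataError(f"malformed header: need columns {sorted(required)}, got {list(df.columns)}")
        x = np.unique(df["x"].to_numpy())
        y = np.unique(df["y"].to_numpy())
        frames = np.unique(df["frame"].to_numpy())
        t = df.sort_values("frame").groupby("frame")["t"].first().to_numpy()
        grid = ScanGrid(x=x, y=y, t=t)
        nt, ny, nx = grid.shape
        if len(df) != nt * ny * nx:
            raise DataError("long-format field is not a complete grid")
        df = df.sort_values(["frame", "y", "x"])
        shape = (nt, ny, nx)
        meta.pop("units", None)
        meta.pop("convention", None)
        return VelocityField2D(
            grid=grid,
            ux=df["ux"].to_numpy().reshape(shape),
            uy=df["uy"].to_numpy().reshape(shape),
            tq=df["tq"].to_numpy().reshape(shape),
            valid=df["valid"].to_numpy().astype(bool).reshape(shape),
            meta=meta,
        )
    if fmt == "hdf5":
        with h5py.File(path, "r") as h5:
            missing = [k for k in ("x", "y", "t", "ux", "uy", "tq", "valid") if k not in h5]
            if missing:
                raise DataError(f"container missing datasets: {missing}")
            meta = json.loads(h5.attrs.get("metadata", "{}"))
            meta.pop("units", None)
            meta.pop("convention", None)
            return VelocityField2D(
                grid=ScanGrid(x=h5["x"][:], y=h5["y"][:], t=h5["t"][:]),
                ux=h5["ux"][:],
                uy=h5["uy"][:],
                tq=h5["tq"][:],
                valid=h5["valid"][:].astype(bool),
                meta=meta,
            )
    raise ParameterError(f"unknown velocity-field format {fmt!r}")


def write_waveform(wf: PulseWaveform, path) -> None:
    """Two-column CSV t,Q plus a JSON sidecar with the defining parameters."""
    path = Path(path)
    pd.DataFrame({"t": wf.time, "Q": wf.flow}).to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "period": wf.period,
                "pulse_duration": wf.pulse_duration,
                "ramp_fraction": wf.ramp_fraction,
                "peak_flow": wf.peak_flow,
            },
            indent=1,
        ),
        encoding="utf-8",
    )


def read_waveform(path) -> PulseWaveform:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise DataError(f"waveform sidecar missing: {sidecar}")
    params = json.loads(sidecar.read_text(encoding="utf-8"))
    return PulseWaveform(
        period=params["period"],
        pulse_duration=params["pulse_duration"],
        ramp_fraction=params["ramp_fraction"],
        peak_flow=params["peak_flow"],
        time=df["t"].to_numpy(),
        flow=df["Q"].to_numpy(),
    )


def write_phantom_result(result, path, pressure_unit: str = "mmHg") -> None:
    """CSV export t,p_in,p_out,q_in,q_out (pressures converted to mmHg by default)."""
    if pressure_unit not in ("mmHg", "Pa"):
        raise ParameterError(f"pressure_unit must be 'mmHg' or 'Pa', got {pressure_unit!r}")
    conv = (lambda p: pa_to_mmhg(p)) if pressure_unit == "mmHg" else (lambda p: p)
    pd.DataFrame(
        {
            "t": result.time,
            f"p_in_{pressure_unit}": conv(result.p_in),
            f"p_out_{pressure_unit}": conv(result.p_out),
            "q_in": result.q_in,
            "q_out": result.q_out,
        }
    ).to_csv(path, index=False)


def write_trace(trace: PressureTrace, path) -> None:
    df = pd.DataFrame({"t": trace.time, "pressure_mmHg": trace.pressure})
    if trace.label:
        df["label"] = trace.label
    df.to_csv(path, index=False)


def read_trace(path) -> PressureTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    if "t" not in df.columns or "pressure_mmHg" not in df.columns:
        raise DataError("trace file needs columns t,pressure_mmHg(,label)")
    label = str(df["label"].iloc[0]) if "label" in df.columns else ""
    return PressureTrace(time=df["t"].to_numpy(), pressure=df["pressure_mmHg"].to_numpy(), label=label)


# ---------------------------------------------------------------------------
# Run configuration and logging.
# ---------------------------------------------------------------------------

_PACKAGE_VERSION = "0.1.0"
STOCHASTIC_SUBCOMMANDS = {"emulate-bsi", "simulate-phantom"}


@dataclass
class RunConfig:
    """Serializable description of one CLI run."""

    subcommand: str
    parameters: dict = field(default_factory=dict)
    seed: int | None = None
    version: str = _PACKAGE_VERSION
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)

    def to_mapping(self) -> dict:
        return {
            "subcommand": self.subcommand,
            "parameters": self.parameters,
            "seed": self.seed,
            "version": self.version,
            "inputs": list(self.inputs),
            "outputs": list(self.outputs),
        }

    def save(self, path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_mapping(), indent=1, sort_keys=True)
            if path.suffix.lower() == ".json"
            else yaml.safe_dump(self.to_mapping(), sort_keys=True)
        )
        path.write_text(text, encoding="utf-8")

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict) or "subcommand" not in data:
            raise DataError(f"config {path} must be a mapping with a 'subcommand' key")
        return cls(
            subcommand=data["subcommand"],
            parameters=data.get("parameters", {}),
            seed=data.get("seed"),
            version=data.get("version", _PACKAGE_VERSION),
            inputs=data.get("inputs", []),
            outputs=data.get("outputs", []),
        )

    def require_seed(self) -> None:
        if self.subcommand in STOCHASTIC_SUBCOMMANDS and self.seed is None:
            raise ParameterError(f"subcommand {self.subcommand!r} is stochastic and requires an explicit seed")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunLog:
    """Timestamped events plus an output manifest with content checksums."""

    config: RunConfig
    events: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def event(self, message: str) -> None:
        self.events.append({"t": _time.strftime("%Y-%m-%dT%H:%M:%S"), "message": message})

    def warn(self, message: str) -> None:
        self.warnings.append(message)
        self.event(f"WARNING: {message}")

    def register_output(self, path) -> None:
        path = Path(path)
        self.manifest[str(path)] = sha256_file(path)

    def to_mapping(self) -> dict:
        return {
            "config": self.config.to_mapping(),
            "events": self.events,
            "warnings": self.warnings,
            "manifest": self.manifest,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_mapping(), indent=1, sort_keys=True), encoding="utf-8")

    @classmethod
    def load(cls, path) -> "RunLog":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        c = data.get("config", {})
        cfg = RunConfig(
            subcommand=c.get("subcommand", ""),
            parameters=c.get("parameters", {}),
            seed=c.get("seed"),
            version=c.get("version", _PACKAGE_VERSION),
            inputs=c.get("inputs", []),
            outputs=c.get("outputs", []),
        )
        return cls(config=cfg, events=data.get("events", []), warnings=data.get("warnings", []), manifest=data.get("manifest", {}))
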