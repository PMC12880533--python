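"""Bit-stable file I/O: sensor streams, labeled datasets, thermal fields.

CSV tables are written with 17 significant digits so that a write-read
round trip reproduces the floating-point values exactly.  Thermal fields
travel in NumPy's portable ``.npz`` container together with their grid
metadata (spacing, origin, material labels, velocities).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .frontend import SensorStream
from .grid import SimulationGrid
from .solver import ThermalField

__all__ = [
    "write_stream_csv",
    "read_stream_csv",
    "write_field",
    "read_field",
    "write_folds_csv",
    "read_folds_csv",
    "write_manifest",
]

_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    """Malformed file content, carrying the offending line number."""


def write_stream_csv(stream: SensorStream, path) -> None:
    """Columns: time_s then the channel names; row 2 carries the units."""
    path = Path(path)
    cols = ["time_s", *stream.channel_names]
    units = ["s", *([stream.units] * len(stream.channel_names))]
    with open(path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        fh.write("# units," + ",".join(units[1:]) + "\n")
        data = np.column_stack([stream.timestamps, stream.values])
        np.savetxt(fh, data, fmt=_FLOAT_FMT, delimiter=",")


def read_stream_csv(path) -> SensorStream:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        if not header or header[0] != "time_s":
            raise ParseError(f"{path}:1: expected header starting with time_s")
        units_line = fh.readline().strip()
        if not units_line.startswith("# units,"):
            raise ParseError(f"{path}:2: expected a '# units' row")
        units = units_line.split(",")[1]
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    if data.size == 0:
        data = np.empty((0, len(header)))
    t = data[:, 0]
    rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 20.0
    return SensorStream(round(rate, 6), t, data[:, 1:], units, tuple(header[1:]))


def write_field(field: ThermalField, path) -> None:
    np.savez_compressed(
        path,
        temperature=field.temperature,
        spacing=field.grid.spacing,
        origin=field.grid.origin,
        material=field.grid.material,
        velocity_x=field.grid.velocity_x,
        steady=field.steady,
        time=field.time,
    )


def read_field(path) -> ThermalField:
    with np.load(path, allow_pickle=False) as z:
        grid = SimulationGrid(
            spacing=float(z["spacing"]),
            origin=z["origin"],
            material=z["material"],
            velocity_x=z["velocity_x"],
        )
        return ThermalField(
            temperature=z["temperature"],
            grid=grid,
            steady=bool(z["steady"]),
            time=float(z["time"]),
        )


def write_folds_csv(folds, path) -> None:
    pd.DataFrame(
        {"condition_id": list(folds.folds), "fold": list(folds.folds.values())}
    ).to_csv(path, index=False)


def read_folds_csv(path):
    from .datasets import FoldAssignment

    frame = pd.read_csv(path)
    mapping = dict(zip(frame["condition_id"], frame["fold"].astype(int)))
    return FoldAssignment(mapping, int(frame["fold"].max()) + 1)


def write_multimodal_record(record, directory, name: str) -> None:
    """Store one cardio record as paired CSVs plus a manifest entry.

    ``<name>_1hz.csv`` holds time_s, flow_mm_s, sp_ref_mmhg, dp_ref_mmhg;
    ``<name>_128hz.csv`` holds time_s, ppg.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n = record.duration
    slow = pd.DataFrame({
        "time_s": np.arange(n, dtype=float),
        "flow_mm_s": record.flow,
        "sp_ref_mmhg": record.sp,
        "dp_ref_mmhg": record.dp,
    })
    slow.to_csv(directory / f"{name}_1hz.csv", index=False, float_format=_FLOAT_FMT)
    fast = pd.DataFrame({
        "time_s": np.arange(n * 128) / 128.0,
        "ppg": record.ppg,
    })
    fast.to_csv(directory / f"{name}_128hz.csv", index=False, float_format=_FLOAT_FMT)


def read_multimodal_record(directory, name: str):
    from .cardio import MultimodalRecord

    directory = Path(directory)
    slow = pd.read_csv(directory / f"{name}_1hz.csv", float_precision="round_trip")
    fast = pd.read_csv(directory / f"{name}_128hz.csv", float_precision="round_trip")
    return MultimodalRecord(
        flow=slow["flow_mm_s"].to_numpy(),
        ppg=fast["ppg"].to_numpy(),
        sp=slow["sp_ref_mmhg"].to_numpy(),
        dp=slow["dp_ref_mmhg"].to_numpy(),
    )


def write_manifest(path, config: dict, seed: int, extra: dict | None = None) -> None:
    """Record the run's identity: config hash, seed, package versions."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "thermoflow_version": __version__,
        "numpy_version": np.__version__,
        **(extra or {}),
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
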