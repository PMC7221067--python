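"""Readers and writers: delimited-text traces, event tables, sidecars.

Traces travel as CSV (time_s, co2_ppm, activity, temp_C, flow_ml_min) with
a YAML metadata sidecar (fly identity, live mass, baseline windows, ground
truth when synthetic).  All writes are atomic: content goes to a temporary
file in the target directory which is then renamed into place.
"""

from __future__ import annotations

import contextlib
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .respirometry import RespTrace

__all__ = [
    "atomic_write",
    "write_trace",
    "read_trace",
    "write_survival_table",
    "read_survival_table",
    "sidecar_path",
]

TRACE_COLUMNS = ["time_s", "co2_ppm", "activity", "temp_C", "flow_ml_min"]


@contextlib.contextmanager
def atomic_write(path: str | Path, mode: str = "w"):
    """Write to a temp file in the destination directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        with contextlib.suppress(OSError):
            os.unlink(tmp)
        raise


def sidecar_path(trace_path: str | Path) -> Path:
    p = Path(trace_path)
    return p.with_name(p.stem + ".meta.yaml")


def write_trace(trace: RespTrace, path: str | Path) -> Path:
    """Write trace channels as CSV plus a YAML metadata sidecar."""
    path = Path(path)
    frame = pd.DataFrame({
        "time_s": trace.time_s,
        "co2_ppm": trace.co2_ppm,
        "activity": trace.activity,
        "temp_C": trace.temp_c,
        "flow_ml_min": trace.flow_ml_min,
    })
    with atomic_write(path) as fh:
        frame.to_csv(fh, index=False)
    meta = {
        "fly_id": trace.fly_id,
        "genotype": trace.genotype,
        "age_class": trace.age_class,
        "live_mass_mg": float(trace.live_mass_mg),
        "baseline_pre": [int(i) for i in trace.baseline_pre],
        "baseline_post": [int(i) for i in trace.baseline_post],
        **trace.meta,
    }
    with atomic_write(sidecar_path(path)) as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return path


def read_trace(path: str | Path) -> RespTrace:
    """Read and validate a trace CSV + sidecar into a RespTrace.

    Enforces the 1-Hz contract: a non-unit time step raises with the index
    of the first offending sample, as do missing columns and non-finite
    channel values.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"trace {path.name}: missing columns {missing}")
    for col in ("time_s", "co2_ppm", "activity", "temp_C"):
        bad = np.flatnonzero(~np.isfinite(frame[col].to_numpy(dtype=float)))
        if bad.size:
            raise ValueError(f"trace {path.name}: non-finite {col} at row {int(bad[0])}")
    t = frame["time_s"].to_numpy(dtype=float)
    step = np.diff(t)
    off = np.flatnonzero(~np.isclose(step, 1.0))
    if off.size:
        raise ValueError(
            f"trace {path.name}: non-uniform sampling, first bad step at index {int(off[0])}"
            f" (dt={step[off[0]]:g} s)"
        )
    meta_file = sidecar_path(path)
    if not meta_file.exists():
        raise FileNotFoundError(f"metadata sidecar {meta_file} not found")
    with open(meta_file) as fh:
        meta = yaml.safe_load(fh)
    extra = {k: v for k, v in meta.items()
             if k not in ("fly_id", "genotype", "age_class", "live_mass_mg",
                          "baseline_pre", "baseline_post")}
    return RespTrace(
        time_s=t,
        co2_ppm=frame["co2_ppm"].to_numpy(dtype=float),
        activity=frame["activity"].to_numpy(dtype=float),
        temp_c=frame["temp_C"].to_numpy(dtype=float),
        flow_ml_min=float(frame["flow_ml_min"].iloc[0]),
        baseline_pre=tuple(meta["baseline_pre"]),
        baseline_post=tuple(meta["baseline_post"]),
        fly_id=str(meta["fly_id"]),
        genotype=str(meta["genotype"]),
        age_class=str(meta["age_class"]),
        live_mass_mg=float(meta["live_mass_mg"]),
        meta=extra,
    )


def write_survival_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    with atomic_write(path) as fh:
        table.to_csv(fh, index=False)
    return path


def read_survival_table(path: str | Path, time_unit: str | None = None) -> pd.DataFrame:
    """Read an event table; time_unit comes from the file unless overridden."""
    table = pd.read_csv(path)
    required = {"genotype", "time", "event"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"survival table {Path(path).name}: missing columns {sorted(missing)}")
    if time_unit is not None:
        table["time_unit"] = time_unit
    elif "time_unit" not in table.columns:
        table["time_unit"] = "days"
    return table
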