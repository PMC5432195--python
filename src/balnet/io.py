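"""File I/O: delimited tables, flat key-value configs and run manifests.

Every artifact a driver writes is accompanied by a manifest holding the
complete resolved parameter set and the seeds actually used, so any output
can be regenerated byte-for-byte (apart from timestamps).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .params import NetworkParams
from .simulator import PopulationTrace, SpikeRecord
from . import __version__ as _pkg_version

__all__ = [
    "write_manifest",
    "read_config",
    "write_config",
    "params_from_mapping",
    "write_trace",
    "read_trace",
    "write_spikes",
    "read_spikes",
    "write_table",
]


def _coerce(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    if text.lower() in ("true", "false"):
        return text.lower() == "true"
    if text.lower() in ("none", ""):
        return None
    return text


def read_config(path) -> Dict[str, object]:
    """Read a flat key-value config (one ``key = value`` per line, # comments)."""
    out: Dict[str, object] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        out[key] = _coerce(val)
    return out


def write_config(path, mapping: Dict[str, object]) -> None:
    lines = [f"{k} = {v}" for k, v in mapping.items()]
    Path(path).write_text("\n".join(lines) + "\n")


_TUPLE_FIELDS = {"T"}


def params_from_mapping(mapping: Dict[str, object]) -> NetworkParams:
    """Build NetworkParams from a config mapping; unknown keys are ignored."""
    names = {f.name for f in dataclasses.fields(NetworkParams)}
    kwargs = {}
    for k, v in mapping.items():
        if k not in names:
            continue
        if k in _TUPLE_FIELDS and isinstance(v, str):
            v = tuple(float(s) for s in v.strip("()").split(","))
        elif k in _TUPLE_FIELDS and isinstance(v, (int, float)):
            v = (float(v),) * 4
        kwargs[k] = v
    return NetworkParams(**kwargs)


def write_manifest(path, params: NetworkParams, kind: str = "run", **extra) -> None:
    mapping = {"kind": kind, "version": _pkg_version}
    for f in dataclasses.fields(NetworkParams):
        v = getattr(params, f.name)
        if isinstance(v, tuple):
            v = ",".join(str(x) for x in v)
        mapping[f.name] = v
    mapping.update(extra)
    write_config(path, mapping)


# ---------------------------------------------------------------------------
# Traces and spikes as delimited text

def write_trace(path, trace: PopulationTrace) -> None:
    df = pd.DataFrame(
        {"time_ms": trace.times, "m1": trace.m[:, 0], "m2": trace.m[:, 1],
         "m3": trace.m[:, 2], "m4": trace.m[:, 3]}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_trace(path) -> PopulationTrace:
    df = pd.read_csv(path, sep="\t")
    return PopulationTrace(times=df["time_ms"].to_numpy(),
                           m=df[["m1", "m2", "m3", "m4"]].to_numpy())


def write_spikes(path, spikes: SpikeRecord) -> None:
    df = pd.DataFrame({"time_ms": spikes.times, "population": spikes.populations,
                       "neuron": spikes.indices})
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_spikes(path) -> SpikeRecord:
    df = pd.read_csv(path, sep="\t")
    return SpikeRecord(times=df["time_ms"].to_numpy(),
                       populations=df["population"].to_numpy(np.int8),
                       indices=df["neuron"].to_numpy(np.int32))


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
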