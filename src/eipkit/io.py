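"""File formats: amplitude tables, protocol tables, mechanism sidecars, traces.

All tabular outputs are plain delimited text with a fixed header; provenance
(seed, config hash) is carried in ``#``-prefixed comment lines above the
header and ignored on read.  Full traces go to an HDF5 container with one
group per sweep.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .channel import CompoundMechanism
from .protocol import ProtocolConfig, VoltageProtocol
from .traces import SweepTrace

__all__ = [
    "config_hash",
    "write_amplitudes",
    "read_amplitudes",
    "write_protocol_table",
    "read_protocol_table",
    "write_protocol_config",
    "read_protocol_config",
    "write_mechanism",
    "read_mechanism",
    "write_traces_h5",
    "read_traces_h5",
    "write_json",
    "read_json",
]

_AMPLITUDE_BASE = ["sweep_index", "time_s", "pulse_index", "amplitude_nA"]


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _write_csv_with_header(
    df: pd.DataFrame, path: Path, provenance: Optional[Mapping] = None
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def write_amplitudes(
    df: pd.DataFrame, path, provenance: Optional[Mapping] = None
) -> None:
    missing = set(_AMPLITUDE_BASE) - set(df.columns)
    if missing:
        raise ValueError(f"amplitude table is missing columns: {sorted(missing)}")
    _write_csv_with_header(df, Path(path), provenance)


def read_amplitudes(path, n_pulses_expected: Optional[int] = 17) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = set(_AMPLITUDE_BASE) - set(df.columns)
    if missing:
        raise ValueError(f"amplitude table is missing columns: {sorted(missing)}")
    if n_pulses_expected is not None:
        got = df["pulse_index"].nunique()
        if got != n_pulses_expected:
            raise ValueError(
                f"amplitude table has {got} pulse indices, expected "
                f"{n_pulses_expected}"
            )
    return df


def write_protocol_table(protocol: VoltageProtocol, path) -> None:
    """Flat one-row-per-segment serialization of a protocol."""
    _write_csv_with_header(
        protocol.to_frame(), Path(path),
        {"sweep_period_ms": protocol.sweep_period_ms},
    )


def read_protocol_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_protocol_config(protocol: VoltageProtocol, path) -> None:
    """Structured (JSON) protocol serialization; round-trips exactly."""
    write_json(protocol.to_dict(), path)


def read_protocol_config(path) -> VoltageProtocol:
    return VoltageProtocol.from_dict(read_json(path))


def write_mechanism(mech: CompoundMechanism, path) -> None:
    write_json(mech.to_dict(), path)


def read_mechanism(path) -> CompoundMechanism:
    return CompoundMechanism.from_dict(read_json(path))


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))


def read_json(path):
    return json.loads(Path(path).read_text())


def write_traces_h5(traces: Sequence[SweepTrace], path) -> None:
    import h5py

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        for tr in traces:
            g = f.create_group(f"sweep_{tr.sweep_index:05d}")
            g.create_dataset("time_ms", data=tr.time_ms)
            g.create_dataset("current_nA", data=tr.current_nA)


def read_traces_h5(path) -> list[SweepTrace]:
    import h5py

    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            g = f[name]
            out.append(
                SweepTrace(
                    time_ms=g["time_ms"][()],
                    current_nA=g["current_nA"][()],
                    sweep_index=int(name.split("_")[-1]),
                )
            )
    return out
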