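"""File formats and provenance.

Conventions: delimited text is comma-separated with a mandatory header row
and '.' decimals; every physical column carries its unit in the header
(time_s, current_pA, voltage_mV, conductance_nS); recording metadata lives
in a JSON sidecar next to the trace, never in comment lines; all JSON
reports carry a provenance block (package version, config, seed, input
hashes).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .peptide import ChargeStatePeakSet, PeptideRecord
from .ranking import MultimerMetricsTable
from .trace import CurrentTrace, StepEventSet

__all__ = [
    "read_trace",
    "write_trace",
    "read_iv",
    "write_iv",
    "read_metrics",
    "read_fasta",
    "read_peaks",
    "write_events",
    "provenance_block",
    "write_report",
]

TRACE_COLUMNS = ("time_s", "current_pA")
IV_COLUMNS = ("voltage_mV", "current_pA", "level_label")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def _require_numeric(df: pd.DataFrame, columns: Sequence[str], path: Path) -> None:
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"{path}: non-numeric value {df.loc[row, col]!r} "
                f"in column {col!r}, data row {row + 1}"
            )
        df[col] = coerced


def write_trace(trace: CurrentTrace, path: str | Path) -> Path:
    """CSV (time_s, current_pA) plus a JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.times, "current_pA": trace.samples})
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "sampling_rate_hz": trace.sampling_rate_hz,
        "holding_voltage_mV": trace.holding_voltage_mV,
        **trace.metadata,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, default=str))
    return path


def read_trace(path: str | Path) -> CurrentTrace:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    _require_numeric(df, TRACE_COLUMNS, path)
    meta = json.loads(_sidecar_path(path).read_text())
    sampling_rate = meta.pop("sampling_rate_hz")
    voltage = meta.pop("holding_voltage_mV")
    return CurrentTrace(
        samples=df["current_pA"].to_numpy(),
        sampling_rate_hz=sampling_rate,
        holding_voltage_mV=voltage,
        metadata=meta,
    )


def write_iv(points: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    points.to_csv(path, index=False, float_format="%.17g")
    return path


def read_iv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in IV_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if "level_label" not in df.columns:
        df["level_label"] = "G1"
    _require_numeric(df, IV_COLUMNS[:2], path)
    return df


def read_metrics(path: str | Path) -> MultimerMetricsTable:
    """Metrics table from JSON (list of records) or delimited text."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        frame = pd.DataFrame(json.loads(path.read_text()))
    else:
        frame = pd.read_csv(path, float_precision="round_trip")
    return MultimerMetricsTable(frame)


def read_fasta(
    path: str | Path,
    disulfide_pairs: Sequence[tuple[int, int]] = (),
) -> list[PeptideRecord]:
    """All records from a FASTA file, sequences normalised to upper case.

    Disulfide pairs, when given, are applied to every record (they are not
    representable in FASTA itself).
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            PeptideRecord(rec.id, str(rec.seq).upper(), tuple(disulfide_pairs))
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def read_peaks(path: str | Path) -> ChargeStatePeakSet:
    """Peak list from two-column delimited text (charge, mz) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return ChargeStatePeakSet(tuple((int(p["charge"]), float(p["mz"])) for p in data))
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"charge", "mz"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns charge, mz")
    _require_numeric(df, ("charge", "mz"), path)
    return ChargeStatePeakSet(tuple(zip(df["charge"].astype(int), df["mz"])))


def write_events(events: StepEventSet, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": events.times,
            "delta_pA": events.amplitudes_pA,
            "delta_nS": events.conductances_nS,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def provenance_block(
    config: Optional[dict] = None,
    seed: Optional[int] = None,
    input_paths: Sequence[str | Path] = (),
) -> dict:
    hashes = {}
    for p in input_paths:
        p = Path(p)
        hashes[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()
    return {
        "package": "porescribe",
        "version": __version__,
        "config": _jsonable(config or {}),
        "seed": seed,
        "input_sha256": hashes,
    }


def write_report(result: Any, path: str | Path, provenance: Optional[dict] = None) -> Path:
    """JSON report: {'provenance': ..., 'result': ...}."""
    path = Path(path)
    payload = {"provenance": provenance or provenance_block(), "result": _jsonable(result)}
    path.write_text(json.dumps(payload, indent=2))
    return path
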