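"""CSV dialects and provenance sidecars for the pipeline.

All files are plain comma-separated text with a fixed header; units are
part of the column names. Censored concentrations are encoded as the
literal token "<LLOQ" so below-quantitation points survive a round trip
(write then read restores the canonical form byte-for-byte).
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .adme import DialysisPair, S9Result, TissueSample
from .biotransform import PeakRecord
from .exceptions import (
    MissingColumnError,
    NegativeConcentrationError,
    NonMonotoneTimeError,
)
from .records import ConcProfile, DoseEvent, ExcretionRecord

__all__ = [
    "read_conc_csv",
    "write_conc_csv",
    "read_peaklist_csv",
    "write_peaklist_csv",
    "read_excretion_csv",
    "write_excretion_csv",
    "read_dialysis_csv",
    "read_s9_csv",
    "read_tissue_csv",
    "write_results",
    "write_provenance",
    "config_hash",
]

CENSORED_TOKEN = "<LLOQ"

CONC_COLUMNS = [
    "subject_id",
    "route",
    "dose_mg_kg",
    "matrix",
    "time_min",
    "conc_ug_ml",
    "lloq_ug_ml",
]

PEAK_COLUMNS = ["peak_id", "precursor_mz", "rt_min", "fragments", "sources"]

EXCRETION_COLUMNS = ["subject_id", "ae_0_24_pct", "gi_24_pct", "urine_amount_ug"]


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def _require_columns(header: Sequence[str], required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise MissingColumnError(f"{path}: missing columns {missing}")


def write_conc_csv(
    profiles: Iterable[ConcProfile],
    dose_events: Iterable[DoseEvent],
    path: str | Path,
) -> None:
    """Write concentration-time profiles with their dose events."""
    path = Path(path)
    doses = {d.subject_id: d for d in dose_events}
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CONC_COLUMNS)
        for p in profiles:
            d = doses[p.subject_id]
            for t, c, cens in zip(p.times, p.concs, p.censored):
                writer.writerow(
                    [
                        p.subject_id,
                        d.route,
                        _fmt(d.dose),
                        p.matrix,
                        _fmt(t),
                        CENSORED_TOKEN if cens else _fmt(c),
                        _fmt(p.lloq),
                    ]
                )


def read_conc_csv(path: str | Path) -> tuple[list[ConcProfile], list[DoseEvent]]:
    """Read profiles and dose events; validates ordering and signs."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames or [], CONC_COLUMNS, path)
        rows = list(reader)
    profiles: list[ConcProfile] = []
    dose_events: list[DoseEvent] = []
    by_subject: dict[str, list[dict]] = {}
    order: list[str] = []
    for row in rows:
        sid = row["subject_id"]
        if sid not in by_subject:
            by_subject[sid] = []
            order.append(sid)
        by_subject[sid].append(row)
    for sid in order:
        srows = by_subject[sid]
        times, concs, cens = [], [], []
        for row in srows:
            t = float(row["time_min"])
            if times and t <= times[-1]:
                raise NonMonotoneTimeError(
                    f"{path}: subject {sid}: time {t} not after {times[-1]}"
                )
            times.append(t)
            raw = row["conc_ug_ml"].strip()
            if raw == CENSORED_TOKEN:
                concs.append(np.nan)
                cens.append(True)
            else:
                value = float(raw)
                if value < 0:
                    raise NegativeConcentrationError(
                        f"{path}: subject {sid}: negative concentration {value}"
                    )
                concs.append(value)
                cens.append(False)
        first = srows[0]
        profiles.append(
            ConcProfile(
                subject_id=sid,
                times=np.array(times),
                concs=np.array(concs),
                censored=np.array(cens),
                lloq=float(first["lloq_ug_ml"]),
                matrix=first["matrix"],
            )
        )
        dose_events.append(
            DoseEvent(subject_id=sid, route=first["route"], dose=float(first["dose_mg_kg"]))
        )
    return profiles, dose_events


def write_peaklist_csv(peaks: Iterable[PeakRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PEAK_COLUMNS)
        for p in peaks:
            writer.writerow(
                [
                    p.peak_id,
                    _fmt(p.precursor_mz),
                    _fmt(p.rt),
                    ";".join(_fmt(f) for f in p.fragments),
                    ";".join(p.sources),
                ]
            )


def read_peaklist_csv(path: str | Path) -> list[PeakRecord]:
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames or [], PEAK_COLUMNS, path)
        peaks = []
        for row in reader:
            frags = tuple(
                float(f) for f in row["fragments"].split(";") if f.strip()
            )
            sources = tuple(s for s in row["sources"].split(";") if s.strip())
            peaks.append(
                PeakRecord(
                    peak_id=row["peak_id"],
                    precursor_mz=float(row["precursor_mz"]),
                    rt=float(row["rt_min"]),
                    fragments=frags,
                    sources=sources,
                )
            )
    return peaks


def write_excretion_csv(records: Iterable[ExcretionRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(EXCRETION_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.subject_id,
                    _fmt(r.ae_0_24_pct),
                    _fmt(r.gi_24_pct),
                    "" if r.urine_amount_ug is None else _fmt(r.urine_amount_ug),
                ]
            )


def read_excretion_csv(path: str | Path) -> list[ExcretionRecord]:
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames or [], EXCRETION_COLUMNS[:3], path)
        records = []
        for row in reader:
            urine = row.get("urine_amount_ug", "") or ""
            records.append(
                ExcretionRecord(
                    subject_id=row["subject_id"],
                    ae_0_24_pct=float(row["ae_0_24_pct"]),
                    gi_24_pct=float(row["gi_24_pct"]),
                    urine_amount_ug=float(urine) if urine.strip() else None,
                )
            )
    return records


def read_dialysis_csv(path: str | Path) -> list[DialysisPair]:
    path = Path(path)
    cols = ["plasma_side_conc", "buffer_side_conc", "spiked_conc"]
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames or [], cols, path)
        return [
            DialysisPair(
                plasma_side_conc=float(r["plasma_side_conc"]),
                buffer_side_conc=float(r["buffer_side_conc"]),
                spiked_conc=float(r["spiked_conc"]),
            )
            for r in reader
        ]


def read_s9_csv(path: str | Path) -> list[S9Result]:
    path = Path(path)
    cols = ["tissue", "spiked_conc", "remaining_conc"]
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames or [], cols, path)
        return [
            S9Result(
                tissue=r["tissue"],
                spiked_conc=float(r["spiked_conc"]),
                remaining_conc=float(r["remaining_conc"]),
            )
            for r in reader
        ]


def read_tissue_csv(path: str | Path) -> list[TissueSample]:
    path = Path(path)
    cols = ["tissue", "time_min", "conc_ug_ml", "paired_plasma_conc", "dilution_factor"]
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames or [], cols, path)
        return [
            TissueSample(
                tissue=r["tissue"],
                time=float(r["time_min"]),
                conc=float(r["conc_ug_ml"]),
                paired_plasma_conc=float(r["paired_plasma_conc"]),
                dilution_factor=float(r["dilution_factor"]),
            )
            for r in reader
        ]


def write_results(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy results table as CSV (stable float formatting)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.10g")


def write_provenance(path: str | Path, payload: Mapping) -> None:
    """JSON sidecar recording what produced a data file (spec + seed)."""
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))


def config_hash(payload: Mapping) -> str:
    """Short stable hash of a configuration mapping, for run logs."""
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
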