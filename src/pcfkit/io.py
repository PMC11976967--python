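"""Readers and writers for the pipeline's tabular and FASTA formats.

Tables are delimited text (comma or tab, auto-detected), UTF-8, period
decimal separator.  Thousands separators are tolerated on input (count
columns in published tables use them) but never emitted.  FASTA IO goes
through Bio.SeqIO; record ids are the first whitespace-delimited token of
the header and sequences are uppercased on read.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .edx import EDXRegionCounts, RegionComposition
from .errors import SchemaError
from .heme import ProteinRecord
from .isotope import IsotopePattern
from .iv import IVSweep
from .morphometry import VesicleObservation

__all__ = [
    "read_table",
    "write_table",
    "read_fasta",
    "write_fasta",
    "read_iv_sweeps",
    "write_iv_sweeps",
    "read_edx_regions",
    "read_isotope_patterns",
    "read_vesicles",
    "write_run_summary",
]


def _detect_delimiter(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_table(
    path: str | Path,
    schema: Mapping[str, Callable[[str], object]],
    optional: Sequence[str] = (),
) -> pd.DataFrame:
    """Read a delimited table and validate it against a column schema.

    ``schema`` maps required column names to converters (e.g. ``float``);
    columns listed in ``optional`` are converted only when present.  Errors
    name the offending column, file and 1-based data row.  A header-only
    file yields an empty frame, not an error.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    df = pd.read_csv(path, sep=_detect_delimiter(path), dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    required = [c for c in schema if c not in optional]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    for col, conv in schema.items():
        if col not in df.columns:
            continue
        converted = []
        for row_idx, raw in enumerate(df[col], start=1):
            if isinstance(raw, str):
                raw = raw.strip().replace(",", "") if conv in (float, int) else raw.strip()
            try:
                converted.append(conv(raw))
            except (TypeError, ValueError) as exc:
                raise SchemaError(
                    f"{path}: column {col!r}, row {row_idx}: cannot parse {raw!r}"
                ) from exc
        df[col] = converted
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Multi-record protein FASTA -> validated, uppercased records."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SchemaError(f"{path}: duplicate protein id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq)))
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Stage-specific readers

_IV_SCHEMA = {
    "sample_id": str,
    "strain": str,
    "gap_um": float,
    "voltage_V": float,
    "current_A": float,
}


def read_iv_sweeps(path: str | Path) -> list[IVSweep]:
    """Long-format sweep table -> one IVSweep per sample_id (input order kept)."""
    df = read_table(path, _IV_SCHEMA)
    sweeps = []
    for sid, grp in df.groupby("sample_id", sort=False):
        sweeps.append(
            IVSweep(
                sample_id=str(sid),
                strain_label=str(grp["strain"].iloc[0]),
                voltages=grp["voltage_V"].to_numpy(float),
                currents=grp["current_A"].to_numpy(float),
                gap_length_um=float(grp["gap_um"].iloc[0]),
            )
        )
    return sweeps


def write_iv_sweeps(sweeps: Sequence[IVSweep], path: str | Path) -> None:
    rows = []
    for s in sweeps:
        for v, i in zip(s.voltages, s.currents):
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "strain": s.strain_label,
                    "gap_um": s.gap_length_um,
                    "voltage_V": v,
                    "current_A": i,
                }
            )
    write_table(pd.DataFrame(rows), path)


_EDX_SCHEMA = {
    "section_id": str,
    "strain": str,
    "element": str,
    "ka_counts": float,
    "percent": float,
    "outlier": int,
}


def read_edx_regions(
    path: str | Path,
) -> tuple[list[EDXRegionCounts], list[RegionComposition]]:
    """Long-format EDX table -> count records, plus composition records for
    rows that carry a ``percent`` column."""
    df = read_table(path, _EDX_SCHEMA, optional=("percent", "outlier"))
    counts_out: list[EDXRegionCounts] = []
    comps_out: list[RegionComposition] = []
    for sid, grp in df.groupby("section_id", sort=False):
        outlier = bool(int(grp["outlier"].iloc[0])) if "outlier" in grp else False
        counts_out.append(
            EDXRegionCounts(
                section_id=str(sid),
                strain_label=str(grp["strain"].iloc[0]),
                counts={str(r.element): float(r.ka_counts) for r in grp.itertuples()},
                outlier_flag=outlier,
            )
        )
        if "percent" in grp.columns and not grp["percent"].isna().any():
            comps_out.append(
                RegionComposition(
                    section_id=str(sid),
                    strain_label=str(grp["strain"].iloc[0]),
                    percents={str(r.element): float(r.percent) for r in grp.itertuples()},
                    outlier=outlier,
                )
            )
    return counts_out, comps_out


_ISOTOPE_SCHEMA = {"sample_id": str, "isotope": str, "count": float}


def read_isotope_patterns(path: str | Path) -> list[IsotopePattern]:
    df = read_table(path, _ISOTOPE_SCHEMA)
    patterns = []
    for sid, grp in df.groupby("sample_id", sort=False):
        patterns.append(
            IsotopePattern(
                counts={str(r.isotope): float(r.count) for r in grp.itertuples()},
                sample_id=str(sid),
            )
        )
    return patterns


_VESICLE_SCHEMA = {"diameter_nm": float, "attachment": str}


def read_vesicles(path: str | Path) -> list[VesicleObservation]:
    df = read_table(path, _VESICLE_SCHEMA)
    return [
        VesicleObservation(diameter_nm=float(r.diameter_nm), attachment=str(r.attachment))
        for r in df.itertuples()
    ]


def write_run_summary(summary: dict, path: str | Path) -> None:
    """Machine-readable run summary (inputs, seed, counts, headline stats)."""

    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
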