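"""Readers and writers for the pipeline's on-disk TSV formats.

Conventions
-----------
* Junction and event tables use BED-style 0-based half-open intron
  coordinates; PAS annotation files use 1-based positions (single-base
  cleavage sites). Each reader validates its own convention.
* All files are tab-separated with a header row; lines starting with
  ``#`` are comments (run metadata). gzip is handled transparently by
  extension.
* Malformed rows are rejected with their line number; unknown extra
  columns are accepted with a warning for forward compatibility.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .apa import PASAnnotation, order_pas
from .splicing import JUNCTION_COLUMNS, CrypticEvent

__all__ = [
    "read_junction_table",
    "write_junction_table",
    "read_pas_annotation",
    "write_pas_annotation",
    "read_pas_quant",
    "write_pas_quant",
    "read_count_matrix",
    "write_count_matrix",
    "read_event_defs",
    "write_event_defs",
    "read_groups",
    "write_groups",
    "read_psi_table",
    "write_psi_table",
    "write_table",
]


class ParseError(ValueError):
    """A file failed validation; the message names the offending line."""


def _read_tsv(path: str | Path, required: list[str], dtypes: dict | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=dtypes)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{path}: ignoring unknown columns {extra}", stacklevel=3)
    return df


def _line(df_index: int) -> int:
    # +2: header line plus 1-based numbering (comment lines not counted)
    return int(df_index) + 2


def read_junction_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format junction table (0-based half-open coordinates)."""
    df = _read_tsv(path, JUNCTION_COLUMNS)
    df = df[JUNCTION_COLUMNS].copy()
    df["strand"] = df["strand"].astype(str).replace({"unknown": "."})
    bad_strand = ~df["strand"].isin(["+", "-", "."])
    if bad_strand.any():
        raise ParseError(f"{path}: invalid strand at line {_line(df.index[bad_strand][0])}")
    for col in ("start", "end", "count", "min_anchor"):
        values = pd.to_numeric(df[col], errors="coerce")
        if values.isna().any():
            raise ParseError(f"{path}: non-numeric {col} at line {_line(df.index[values.isna()][0])}")
        df[col] = values.astype(int)
    bad = df["start"] >= df["end"]
    if bad.any():
        raise ParseError(f"{path}: start >= end at line {_line(df.index[bad][0])}")
    for col, floor in (("count", 0), ("min_anchor", 0), ("start", 0)):
        bad = df[col] < floor
        if bad.any():
            raise ParseError(f"{path}: negative {col} at line {_line(df.index[bad][0])}")
    return df.reset_index(drop=True)


def write_junction_table(junctions: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    _write(junctions[JUNCTION_COLUMNS], path, header, index=False)


def read_pas_annotation(path: str | Path) -> dict[str, PASAnnotation]:
    """Read PAS annotations (1-based positions) into ordered annotations."""
    df = _read_tsv(path, ["chrom", "position", "strand", "gene_id", "site_id"])
    bad = pd.to_numeric(df["position"], errors="coerce").isna() | (df["position"] < 1)
    if bad.any():
        raise ParseError(f"{path}: invalid 1-based position at line {_line(df.index[bad][0])}")
    annotations = {}
    for gene_id, group in df.groupby("gene_id", sort=False):
        strands = group["strand"].unique()
        chroms = group["chrom"].unique()
        if len(strands) > 1 or len(chroms) > 1:
            raise ParseError(f"{path}: gene {gene_id} spans multiple strands or chromosomes")
        ann = PASAnnotation(
            gene_id=str(gene_id),
            chrom=str(chroms[0]),
            strand=str(strands[0]),
            pas_positions=tuple(int(p) for p in group["position"]),
        )
        annotations[str(gene_id)] = order_pas(ann)
    return annotations


def write_pas_annotation(annotations: dict[str, PASAnnotation], path: str | Path, header: str | None = None) -> None:
    rows = []
    for ann in annotations.values():
        for i, pos in enumerate(ann.pas_positions):
            rows.append(
                {
                    "chrom": ann.chrom,
                    "position": pos,
                    "strand": ann.strand,
                    "gene_id": ann.gene_id,
                    "site_id": f"{ann.gene_id}_PAS{i + 1}",
                }
            )
    _write(pd.DataFrame(rows), path, header, index=False)


def read_pas_quant(path: str | Path) -> pd.DataFrame:
    """Read a per-PAS TPM table indexed by (gene_id, pas_index)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("gene_id", "pas_index"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col}")
    dup = df.duplicated(subset=["gene_id", "pas_index"])
    if dup.any():
        raise ParseError(f"{path}: duplicate (gene_id, pas_index) row at line {_line(df.index[dup][0])}")
    out = df.set_index(["gene_id", "pas_index"])
    sample_cols = list(out.columns)
    if not sample_cols:
        raise ParseError(f"{path}: no sample columns found")
    values = out.to_numpy(dtype=float)
    if np.isnan(values).any() or (values < 0).any():
        raise ParseError(f"{path}: TPM values must be non-negative numbers")
    return out.astype(float)


def write_pas_quant(quant: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    _write(quant.reset_index(), path, header, index=False)


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample integer count matrix."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "gene_id" not in df.columns:
        raise ParseError(f"{path}: missing required column gene_id")
    dup = df.duplicated(subset=["gene_id"])
    if dup.any():
        raise ParseError(f"{path}: duplicate gene row at line {_line(df.index[dup][0])}")
    out = df.set_index("gene_id")
    values = out.to_numpy()
    if (values < 0).any():
        raise ParseError(f"{path}: counts must be non-negative")
    return out.astype(np.int64)


def write_count_matrix(counts: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    _write(counts.reset_index(), path, header, index=False)


def read_event_defs(path: str | Path) -> list[CrypticEvent]:
    """Read cryptic-event definitions (role = canonical | cryptic per junction)."""
    df = _read_tsv(path, ["event_id", "role", "chrom", "start", "end", "strand"])
    bad = df["start"] >= df["end"]
    if bad.any():
        raise ParseError(f"{path}: start >= end at line {_line(df.index[bad][0])}")
    events = []
    for event_id, group in df.groupby("event_id", sort=False):
        canonical = group[group["role"] == "canonical"]
        cryptic = group[group["role"] == "cryptic"]
        if len(canonical) != 1:
            raise ParseError(f"{path}: event {event_id} needs exactly one canonical junction")
        if len(cryptic) < 1:
            raise ParseError(f"{path}: event {event_id} needs at least one cryptic junction")
        unknown = set(group["role"]) - {"canonical", "cryptic"}
        if unknown:
            raise ParseError(f"{path}: event {event_id} has unknown roles {sorted(unknown)}")
        events.append(
            CrypticEvent(
                event_id=str(event_id),
                chrom=str(canonical["chrom"].iloc[0]),
                strand=str(canonical["strand"].iloc[0]),
                canonical=(int(canonical["start"].iloc[0]), int(canonical["end"].iloc[0])),
                cryptic=tuple((int(s), int(e)) for s, e in zip(cryptic["start"], cryptic["end"])),
            )
        )
    return events


def write_event_defs(events: list[CrypticEvent], path: str | Path, header: str | None = None) -> None:
    rows = []
    for event in events:
        rows.append(
            {
                "event_id": event.event_id,
                "role": "canonical",
                "chrom": event.chrom,
                "start": event.canonical[0],
                "end": event.canonical[1],
                "strand": event.strand,
            }
        )
        for s, e in event.cryptic:
            rows.append(
                {"event_id": event.event_id, "role": "cryptic", "chrom": event.chrom, "start": s, "end": e, "strand": event.strand}
            )
    _write(pd.DataFrame(rows), path, header, index=False)


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a sample -> condition map (two-column TSV)."""
    df = _read_tsv(path, ["sample_id", "condition"])
    dup = df.duplicated(subset=["sample_id"])
    if dup.any():
        raise ParseError(f"{path}: duplicate sample at line {_line(df.index[dup][0])}")
    return dict(zip(df["sample_id"].astype(str), df["condition"].astype(str)))


def write_groups(groups: dict[str, str], path: str | Path, header: str | None = None) -> None:
    df = pd.DataFrame({"sample_id": list(groups), "condition": list(groups.values())})
    _write(df, path, header, index=False)


def read_psi_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "gene_id" not in df.columns:
        raise ParseError(f"{path}: missing required column gene_id")
    return df.set_index("gene_id").astype(float)


def write_psi_table(psi: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    _write(psi.reset_index(), path, header, index=False)


def write_table(df: pd.DataFrame, path: str | Path, header: str | None = None, index: bool = True) -> None:
    """Write a generic result table with an optional ``#`` metadata header."""
    _write(df.reset_index() if index else df, path, header, index=False)


def _write(df: pd.DataFrame, path: str | Path, header: str | None, index: bool) -> None:
    path = Path(path)
    text = df.to_csv(sep="\t", index=index, na_rep="NA")
    prefix = ""
    if header:
        prefix = "".join(f"# {line}\n" for line in header.splitlines())
    if str(path).endswith(".gz"):
        import gzip

        with gzip.open(path, "wt") as fh:
            fh.write(prefix + text)
    else:
        path.write_text(prefix + text)
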