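"""Readers and writers for the delimited and sequence formats the pipeline uses.

Covers peptide identification tables (TSV/CSV), the local bioactive-peptide
reference, parent-protein FASTA, and the TSV/JSON report emitter.  Also exposes
the packaged hydrolysate identification table (114 printed rows; the source
prose claims 113 unique sequences — transcription is verbatim, the discrepancy
is documented, not repaired) and the default modification and reference
resources.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, List, Optional, Tuple

import pandas as pd
from Bio import SeqIO

from .peptide_core import (
    ModificationDelta,
    Peptide,
    SequenceError,
    parse_sequence,
    round_mass,
)

logger = logging.getLogger(__name__)

_DATA_PACKAGE = "snailpep.data"

DEFAULT_COLUMNS = {
    "accession": "accession",
    "sequence": "sequence",
    "reported_mass": "reported_mass",
}

_SEPARATORS = {"tsv": "\t", "csv": ","}


class TableFormatError(ValueError):
    """Malformed or incomplete delimited input."""


@dataclass
class PeptideTable:
    """An ordered collection of peptides read from one source."""

    records: List[Peptide]
    source: str = "<memory>"

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def sequences(self) -> List[str]:
        return [p.sequence for p in self.records]


@dataclass(frozen=True)
class ReferenceEntry:
    sequence: str
    activity_class: str
    source: str


@dataclass
class BioactiveReference:
    """Local stand-in for a curated bioactive-peptide database.

    Entries are validated sequences; duplicates are collapsed with their
    activity classes and sources merged.
    """

    entries: List[ReferenceEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def sequences(self) -> List[str]:
        return [e.sequence for e in self.entries]


def _resolve_sep(dialect: str) -> str:
    try:
        return _SEPARATORS[dialect]
    except KeyError:
        raise TableFormatError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")


def read_peptide_table(
    path,
    dialect: str = "tsv",
    column_map: Optional[dict] = None,
    strict: bool = True,
) -> PeptideTable:
    """Read a peptide identification table.

    Required columns (after ``column_map`` renaming): accession and sequence;
    a reported-mass column is optional.  Strict mode raises on the first bad
    row; permissive mode skips and logs bad rows with their line numbers.
    """
    path = Path(path)
    sep = _resolve_sep(dialect)
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"{path}: empty file")
    for key in ("accession", "sequence"):
        if cols[key] not in df.columns:
            raise TableFormatError(f"{path}: missing required column {cols[key]!r}")
    if df.empty:
        raise TableFormatError(f"{path}: no data rows")
    has_mass = cols["reported_mass"] in df.columns

    records: List[Peptide] = []
    for i, row in df.iterrows():
        line_no = i + 2  # 1-based, after the header line
        try:
            mass = None
            if has_mass and pd.notna(row[cols["reported_mass"]]):
                mass = float(row[cols["reported_mass"]])
            records.append(
                parse_sequence(
                    row[cols["sequence"]],
                    accession=row[cols["accession"]],
                    reported_mass=mass,
                )
            )
        except (SequenceError, TypeError, ValueError) as exc:
            if strict:
                raise TableFormatError(f"{path}: line {line_no}: {exc}") from exc
            logger.warning("%s: line %d skipped: %s", path, line_no, exc)
    return PeptideTable(records=records, source=str(path))


def read_fasta(path) -> List[Tuple[str, str]]:
    """Read a FASTA file into (identifier, uppercased sequence) pairs.

    Identifiers are truncated at the first whitespace; wrapped sequence lines
    are concatenated.  An empty sequence or a file not starting with '>' is
    an error.
    """
    path = Path(path)
    with open(path) as fh:
        head = fh.read(1)
    if head != ">":
        raise TableFormatError(f"{path}: not FASTA (does not start with '>')")
    out: List[Tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise TableFormatError(f"{path}: record {rec.id!r} has empty sequence")
        out.append((rec.id, seq))
    return out


def read_reference(path, dialect: str = "tsv") -> BioactiveReference:
    """Read a bioactive-peptide reference (sequence, activity_class, source).

    Sequences are validated and deduplicated; duplicate rows have their
    activity classes and sources merged (semicolon-joined, sorted).
    An empty file yields an empty reference: downstream, every peptide is
    then flagged novel.
    """
    path = Path(path)
    sep = _resolve_sep(dialect)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError:
        return BioactiveReference(entries=[])
    for col in ("sequence", "activity_class"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing required column {col!r}")
    merged: dict = {}
    for i, row in df.iterrows():
        try:
            pep = parse_sequence(row["sequence"])
        except SequenceError as exc:
            raise TableFormatError(f"{path}: line {i + 2}: {exc}") from exc
        source = row.get("source", "") if isinstance(row, pd.Series) else ""
        if pd.isna(source):
            source = ""
        slot = merged.setdefault(pep.sequence, (set(), set()))
        slot[0].add(str(row["activity_class"]))
        if source:
            slot[1].add(str(source))
    entries = [
        ReferenceEntry(seq, ";".join(sorted(ac)), ";".join(sorted(src)))
        for seq, (ac, src) in merged.items()
    ]
    return BioactiveReference(entries=entries)


def _data_path(name: str) -> Path:
    return Path(resources.files(_DATA_PACKAGE) / name)


def load_table1() -> PeptideTable:
    """The packaged hydrolysate identification fixture (verbatim transcription)."""
    return read_peptide_table(_data_path("table1.tsv"), dialect="tsv")


def table1_checksum() -> str:
    """SHA-256 of the packaged fixture, so silent edits are detectable."""
    return hashlib.sha256(_data_path("table1.tsv").read_bytes()).hexdigest()


def default_reference() -> BioactiveReference:
    """Packaged reference: eight antihypertensive dipeptides plus two
    antioxidant nonapeptides reported from other mollusc hydrolysates."""
    return read_reference(_data_path("bioactive_reference.tsv"), dialect="tsv")


def read_modifications(path=None, dialect: str = "tsv") -> List[ModificationDelta]:
    """Read a modification catalogue (name, delta_da, applicability).

    ``applicability`` is a residue string, or ``*`` for any peptide.  With no
    path the packaged default catalogue is returned.
    """
    path = Path(path) if path is not None else _data_path("modifications.tsv")
    sep = _resolve_sep(dialect)
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("name", "delta_da", "applicability"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing required column {col!r}")
    mods = []
    for _, row in df.iterrows():
        app = row["applicability"].strip()
        applicability = None if app == "*" else frozenset(app)
        mods.append(ModificationDelta(row["name"], float(row["delta_da"]), applicability))
    return mods


REPORT_SCHEMA_VERSION = 1


def write_report(report, path, format: str = "tsv") -> None:
    """Write a pipeline report as TSV (fixed column order, 2-dp masses) or
    JSON (full precision, versioned schema).  Output is deterministic:
    writing the same report twice yields byte-identical files."""
    path = Path(path)
    if format == "tsv":
        rows = report.to_rows()
        columns = list(rows[0].keys()) if rows else []
        with open(path, "w", newline="") as fh:
            fh.write("\t".join(columns) + "\n")
            for row in rows:
                fh.write("\t".join(_format_cell(row[c]) for c in columns) + "\n")
    elif format == "json":
        payload = {"schema_version": REPORT_SCHEMA_VERSION}
        payload.update(report.to_dict())
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return f"{round_mass(value):.2f}"
    return str(value)
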