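"""Readers/writers for the external formats the pipeline touches.

Canonical in-memory records (:class:`TraceRead`, :class:`ReferenceGenome`,
:class:`BedMismatchRow`, :class:`IntervalSet`) live here too, so every other
module can treat I/O as a solved problem.

Coordinate conventions, used everywhere in the package:

* genomic coordinates are 0-based, half-open (BED convention);
* trace coordinates are 0-based in read orientation;
* the 12-column tabular alignment dialect is the single place 1-based
  inclusive coordinates appear, and they are converted on ingestion.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from intervaltree import IntervalTree

__all__ = [
    "Origin",
    "TraceRead",
    "ReferenceGenome",
    "BedMismatchRow",
    "IntervalSet",
    "FormatError",
    "MISMATCH_TYPES",
    "read_fasta",
    "write_fasta",
    "read_qual",
    "write_qual",
    "read_metadata",
    "attach_metadata",
    "write_metadata",
    "write_bed",
    "read_bed_intervals",
    "read_alignment_table",
    "write_alignment_table",
    "complement",
    "revcomp",
]

_VALID = set("ACGTN")
_COMP = str.maketrans("ACGTN", "TGCAN")

#: The 12 ordered base substitutions, read orientation.
MISMATCH_TYPES = tuple(
    f"{x}>{y}" for x in "ACGT" for y in "ACGT" if x != y
)


def complement(base: str) -> str:
    return base.translate(_COMP)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class Origin(str, Enum):
    """Likely molecular origin of a trace (from archive auxiliary info)."""

    DNA = "DNA"
    RNA = "RNA"
    UNKNOWN = "UNKNOWN"

    @classmethod
    def coerce(cls, value) -> "Origin":
        if isinstance(value, Origin):
            return value
        if value is None:
            return cls.UNKNOWN
        v = str(value).strip().upper()
        if v in ("DNA", "RNA"):
            return cls(v)
        return cls.UNKNOWN


@dataclass
class TraceRead:
    """A capillary read: bases, optional per-base phred scores, metadata."""

    trace_id: str
    sequence: str
    quals: list[int] | None = None
    origin: Origin = Origin.UNKNOWN
    center: str = "UNKNOWN"
    organism: str = "UNKNOWN"

    def __post_init__(self) -> None:
        if self.quals is not None:
            if len(self.quals) != len(self.sequence):
                raise ValueError(
                    f"trace {self.trace_id}: {len(self.quals)} quality scores "
                    f"for {len(self.sequence)} bases"
                )
            bad = [q for q in self.quals if not 0 <= q <= 93]
            if bad:
                raise ValueError(
                    f"trace {self.trace_id}: phred scores outside [0, 93]: {bad[:3]}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


class ReferenceGenome:
    """Uppercase reference sequences addressable by (name, 0-based position)."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: dict[str, str] = dict(sequences)

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    @property
    def names(self) -> list[str]:
        return list(self._seqs)

    def length(self, name: str) -> int:
        return len(self._seqs[name])

    def base(self, name: str, pos: int) -> str:
        seq = self._seqs[name]
        if not 0 <= pos < len(seq):
            raise IndexError(f"{name}:{pos} outside [0, {len(seq)})")
        return seq[pos]

    def items(self):
        return self._seqs.items()


@dataclass(frozen=True)
class BedMismatchRow:
    """One mismatch in the BED6+6 output schema.

    Columns past the canonical six: mismatch trace position, run length,
    sequencing center, organism, trace origin.
    """

    chrom: str
    start: int
    end: int
    trace_id: str
    qual: int
    strand: str
    mismatch_type: str
    trace_pos: int
    run_length: int
    center: str = "UNKNOWN"
    organism: str = "UNKNOWN"
    origin: Origin = Origin.UNKNOWN

    def __post_init__(self) -> None:
        if self.end != self.start + 1:
            raise ValueError("a mismatch row covers exactly one base")
        if self.mismatch_type not in MISMATCH_TYPES:
            raise ValueError(f"unknown mismatch type {self.mismatch_type!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


class IntervalSet:
    """Per-chromosome labelled 0-based half-open intervals (may overlap)."""

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}

    def add(self, chrom: str, start: int, end: int, label: str = "") -> None:
        if start >= end:
            raise ValueError(f"empty interval {chrom}:{start}-{end}")
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end, label)

    def overlaps(self, chrom: str, pos: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos))

    def overlaps_interval(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))

    def intervals(self) -> Iterable[tuple[str, int, int, str]]:
        for chrom in sorted(self._trees):
            for iv in sorted(self._trees[chrom]):
                yield chrom, iv.begin, iv.end, iv.data

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


# ---------------------------------------------------------------------------
# FASTA / QUAL


def _sanitize(seq: str) -> str:
    up = seq.upper()
    if set(up) <= _VALID:
        return up
    return "".join(c if c in _VALID else "N" for c in up)


def _structural_check(path) -> None:
    """Cheap pre-scan so malformed FASTA fails with a line number."""
    opener = gzip.open if str(path).endswith(".gz") else open
    seen_header = False
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                if len(stripped) == 1:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                seen_header = True
            elif not seen_header:
                raise FormatError(
                    f"{path}: sequence data before any FASTA header at line {lineno}"
                )
    if not seen_header:
        raise FormatError(f"{path}: no FASTA records found")


def read_fasta(path, as_reference: bool = False):
    """Read FASTA into TraceReads, or a :class:`ReferenceGenome`.

    Sequences are uppercased; characters outside {A,C,G,T,N} become N so the
    downstream N filters are the single place ambiguity is handled.
    """
    _structural_check(path)
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        records[rec.id] = _sanitize(str(rec.seq))
    if as_reference:
        return ReferenceGenome(records)
    return [TraceRead(trace_id=k, sequence=v) for k, v in records.items()]


def write_fasta(records, path, width: int = 70) -> None:
    """Write TraceReads or a ReferenceGenome as FASTA."""
    if isinstance(records, ReferenceGenome):
        items = records.items()
    else:
        items = ((r.trace_id, r.sequence) for r in records)
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_qual(path, traces: Sequence[TraceRead]) -> list[TraceRead]:
    """Attach phred scores from a QUAL file to matching traces (in place).

    Traces with no QUAL record keep ``quals=None``; a QUAL record whose length
    disagrees with its trace is an error naming the trace id.
    """
    by_id = {t.trace_id: t for t in traces}
    try:
        parsed = list(SeqIO.parse(str(path), "qual"))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    for rec in parsed:
        trace = by_id.get(rec.id)
        if trace is None:
            continue
        scores = rec.letter_annotations["phred_quality"]
        if len(scores) != len(trace.sequence):
            raise FormatError(
                f"{path}: QUAL record {rec.id!r} has {len(scores)} scores for a "
                f"{len(trace.sequence)}-base trace"
            )
        trace.quals = [int(q) for q in scores]
    return list(traces)


def write_qual(traces: Iterable[TraceRead], path, per_line: int = 20) -> None:
    with open(path, "w") as fh:
        for t in traces:
            if t.quals is None:
                continue
            fh.write(f">{t.trace_id}\n")
            for i in range(0, len(t.quals), per_line):
                fh.write(" ".join(map(str, t.quals[i : i + per_line])) + "\n")


# ---------------------------------------------------------------------------
# Metadata sidecar

_META_COLS = ["trace_id", "center", "organism", "origin"]


def read_metadata(path) -> pd.DataFrame:
    """Tab-separated per-trace metadata keyed by trace_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: metadata table missing columns {missing}")
    return df.set_index("trace_id")


def attach_metadata(traces: Sequence[TraceRead], meta: pd.DataFrame) -> list[TraceRead]:
    """Fill center/organism/origin from the sidecar; absent rows stay UNKNOWN."""
    for t in traces:
        if t.trace_id in meta.index:
            row = meta.loc[t.trace_id]
            t.center = str(row.get("center", "UNKNOWN"))
            t.organism = str(row.get("organism", "UNKNOWN"))
            t.origin = Origin.coerce(row.get("origin"))
    return list(traces)


def write_metadata(traces: Iterable[TraceRead], path) -> None:
    rows = [
        (t.trace_id, t.center, t.organism, t.origin.value) for t in traces
    ]
    pd.DataFrame(rows, columns=_META_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED

_BED_COLS = [
    "chrom", "start", "end", "trace_id", "qual", "strand",
    "mismatch_type", "trace_pos", "run_length", "center", "organism", "origin",
]


def write_bed(rows: Sequence[BedMismatchRow], path, gz: bool | None = None) -> None:
    """Write mismatch rows as BED6+6, sorted by (chrom, start).

    ``gz=None`` infers compression from a ``.gz`` suffix.
    """
    ordered = sorted(rows, key=lambda r: (r.chrom, r.start, r.trace_id))
    if gz is None:
        gz = str(path).endswith(".gz")
    opener = gzip.open if gz else open
    with opener(path, "wt") as fh:
        for r in ordered:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        r.chrom, r.start, r.end, r.trace_id, r.qual, r.strand,
                        r.mismatch_type, r.trace_pos, r.run_length,
                        r.center, r.organism, r.origin.value,
                    )
                )
                + "\n"
            )


def read_bed_intervals(path) -> IntervalSet:
    """Read a (>=3 column) BED file of annotation intervals, e.g. repeats."""
    out = IntervalSet()
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            parts = stripped.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: fewer than 3 BED columns at line {lineno}")
            label = parts[3] if len(parts) > 3 else ""
            out.add(parts[0], int(parts[1]), int(parts[2]), label)
    return out


# ---------------------------------------------------------------------------
# 12-column tabular alignments (external aligner output)

_ALN_COLS = [
    "query", "subject", "pident", "length", "mismatches", "gapopens",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass
class TabularAlignment:
    """One ingested external placement, coordinates already 0-based half-open."""

    trace_id: str
    chrom: str
    identity: float          # fraction in [0, 1]
    length: int
    n_mismatch: int
    has_indel: bool
    trace_start: int
    trace_end: int
    ref_start: int
    ref_end: int
    strand: str


def read_alignment_table(path) -> list[TabularAlignment]:
    """Ingest 12-column tabular alignments (1-based inclusive on disk).

    ``sstart > send`` encodes a minus-strand placement. Rows with gap opens
    are retained but flagged; the placement filter rejects them.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] != 12:
        raise FormatError(
            f"{path}: expected 12 tab-separated columns, found {df.shape[1]}"
        )
    df.columns = _ALN_COLS
    out = []
    for row in df.itertuples(index=False):
        sstart, send = int(row.sstart), int(row.send)
        if sstart <= send:
            strand, ref_start, ref_end = "+", sstart - 1, send
        else:
            strand, ref_start, ref_end = "-", send - 1, sstart
        out.append(
            TabularAlignment(
                trace_id=str(row.query),
                chrom=str(row.subject),
                identity=float(row.pident) / 100.0,
                length=int(row.length),
                n_mismatch=int(row.mismatches),
                has_indel=int(row.gapopens) > 0,
                trace_start=int(row.qstart) - 1,
                trace_end=int(row.qend),
                ref_start=ref_start,
                ref_end=ref_end,
                strand=strand,
            )
        )
    return out


def write_alignment_table(alignments: Iterable[TabularAlignment], path) -> None:
    """Inverse of :func:`read_alignment_table` (restores 1-based inclusive)."""
    with open(path, "w") as fh:
        for a in alignments:
            if a.strand == "+":
                sstart, send = a.ref_start + 1, a.ref_end
            else:
                sstart, send = a.ref_end, a.ref_start + 1
            fh.write(
                "\t".join(
                    map(
                        str,
                        (
                            a.trace_id, a.chrom, round(a.identity * 100.0, 2),
                            a.length, a.n_mismatch, int(a.has_indel),
                            a.trace_start + 1, a.trace_end, sstart, send,
                            0.0, 0.0,
                        ),
                    )
                )
                + "\n"
            )
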