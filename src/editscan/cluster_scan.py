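"""Mismatch enumeration and same-type run ("cluster") detection.

A run is a maximal block of consecutive mismatches of one substitution type
along a read: matching columns between members do not break it, any mismatch
of another type does. "Consecutive" is consecutive in the ordered mismatch
list, not base-adjacent — runs of five routinely span well over 100 bp.

All mismatch types are reported in read orientation (12 types); complementary
pairs (G>A with C>T, A>G with T>C) are aggregated only in statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import (
    BedMismatchRow,
    MISMATCH_TYPES,
    Origin,
    ReferenceGenome,
    TraceRead,
    revcomp,
)
from .placement import AlignmentRecord

__all__ = [
    "Mismatch",
    "MismatchRun",
    "ScanConfig",
    "enumerate_mismatches",
    "find_runs",
    "apply_span_filter",
    "apply_motif_filter",
    "scan_trace",
    "runs_to_bed_rows",
]


@dataclass(frozen=True)
class Mismatch:
    """One aligned column where trace and reference disagree (neither N).

    ``ref_base`` and both 3-mer motifs are given in read orientation: for a
    minus-strand placement the reference is reverse-complemented. Motifs are
    centered on the mismatch; a motif truncated by a sequence end or touching
    an uncalled base is flagged ``n_context``.
    """

    chrom: str
    ref_pos: int
    trace_pos: int
    ref_base: str
    trace_base: str
    qual: int | None
    trace_motif: str
    ref_motif: str

    def __post_init__(self) -> None:
        if self.ref_base == self.trace_base:
            raise ValueError("not a mismatch: bases agree")

    @property
    def mismatch_type(self) -> str:
        return f"{self.ref_base}>{self.trace_base}"

    @property
    def n_context(self) -> bool:
        return "N" in self.trace_motif or "N" in self.ref_motif


@dataclass
class MismatchRun:
    """A maximal block of consecutive same-type mismatches on one trace."""

    trace_id: str
    mismatch_type: str
    mismatches: list[Mismatch]

    def __post_init__(self) -> None:
        if not self.mismatches:
            raise ValueError("a run holds at least one mismatch")
        if any(m.mismatch_type != self.mismatch_type for m in self.mismatches):
            raise ValueError("run members must share one mismatch type")

    @property
    def length(self) -> int:
        return len(self.mismatches)

    @property
    def span_bp(self) -> int:
        """Trace-coordinate distance between first and last member."""
        pos = [m.trace_pos for m in self.mismatches]
        return max(pos) - min(pos)

    @property
    def motif_uniform(self) -> bool:
        motifs = {m.trace_motif for m in self.mismatches}
        return len(motifs) == 1


@dataclass(frozen=True)
class ScanConfig:
    """Run-detection thresholds.

    ``min_run=5`` with ``motif_uniform`` is the artifact/motif survey;
    ``min_run=3`` (any quality) feeds the quality-set construction.
    """

    min_run: int = 5
    min_span_bp: int = 100
    motif_uniform: bool = False
    drop_n_context: bool = True

    def __post_init__(self) -> None:
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if self.min_span_bp < 0:
            raise ValueError("min_span_bp must be >= 0")


def _motifs(aln: AlignmentRecord, reference: ReferenceGenome,
            trace: TraceRead, trace_pos: int, ref_pos: int) -> tuple[str, str]:
    seq = trace.sequence
    if 1 <= trace_pos <= len(seq) - 2:
        t_motif = seq[trace_pos - 1 : trace_pos + 2]
    else:
        t_motif = "NNN"  # no full 3-mer at a read edge
    ref = reference[aln.chrom]
    if 1 <= ref_pos <= len(ref) - 2:
        r_motif = ref[ref_pos - 1 : ref_pos + 2]
        if aln.strand == "-":
            r_motif = revcomp(r_motif)
    else:
        r_motif = "NNN"
    return t_motif, r_motif


def enumerate_mismatches(
    aln: AlignmentRecord, reference: ReferenceGenome, trace: TraceRead
) -> list[Mismatch]:
    """All mismatching aligned columns, in trace order, N columns skipped."""
    if aln.has_indel:
        raise ValueError("mismatch enumeration requires an ungapped placement")
    ref = reference[aln.chrom]
    if aln.ref_start < 0 or aln.ref_end > len(ref):
        raise ValueError(
            f"{aln.trace_id}: alignment outside {aln.chrom} (corrupt record)"
        )
    seq = trace.sequence
    out: list[Mismatch] = []
    for i in range(aln.length):
        t = aln.trace_start + i
        if aln.strand == "+":
            rp = aln.ref_start + i
            rb = ref[rp]
        else:
            rp = aln.ref_end - 1 - i
            rb = revcomp(ref[rp])
        tb = seq[t]
        if tb == rb or tb == "N" or rb == "N":
            continue
        t_motif, r_motif = _motifs(aln, reference, trace, t, rp)
        out.append(
            Mismatch(
                chrom=aln.chrom, ref_pos=rp, trace_pos=t,
                ref_base=rb, trace_base=tb,
                qual=None if trace.quals is None else trace.quals[t],
                trace_motif=t_motif, ref_motif=r_motif,
            )
        )
    return out


def find_runs(
    mismatches: Sequence[Mismatch],
    cfg: ScanConfig = ScanConfig(),
    trace_id: str = "",
) -> list[MismatchRun]:
    """Maximal same-type blocks in trace order, kept when length >= min_run."""
    ordered = sorted(mismatches, key=lambda m: m.trace_pos)
    runs: list[MismatchRun] = []
    block: list[Mismatch] = []
    for m in ordered:
        if block and m.mismatch_type != block[-1].mismatch_type:
            if len(block) >= cfg.min_run:
                runs.append(MismatchRun(trace_id, block[0].mismatch_type, block))
            block = []
        block.append(m)
    if block and len(block) >= cfg.min_run:
        runs.append(MismatchRun(trace_id, block[0].mismatch_type, block))
    return runs


def apply_span_filter(
    runs: Iterable[MismatchRun], cfg: ScanConfig = ScanConfig()
) -> list[MismatchRun]:
    """Drop runs spanning fewer than ``min_span_bp`` trace bases.

    Short dense clusters are typical of locally bad sequence, not editing.
    """
    return [r for r in runs if r.span_bp >= cfg.min_span_bp]


def apply_motif_filter(
    runs: Iterable[MismatchRun], cfg: ScanConfig = ScanConfig(motif_uniform=True)
) -> list[MismatchRun]:
    """Keep runs whose members all share one trace 3-mer motif.

    With a single substitution type, a uniform trace motif forces a uniform
    reference motif too. Runs containing any N-context member are discarded
    whole when ``drop_n_context``.
    """
    kept = []
    for r in runs:
        if cfg.drop_n_context and any(m.n_context for m in r.mismatches):
            continue
        if r.motif_uniform:
            kept.append(r)
    return kept


def scan_trace(
    aln: AlignmentRecord,
    reference: ReferenceGenome,
    trace: TraceRead,
    cfg: ScanConfig = ScanConfig(),
) -> list[MismatchRun]:
    """Enumerate, detect runs, and apply the configured span/motif filters."""
    runs = find_runs(enumerate_mismatches(aln, reference, trace), cfg, trace.trace_id)
    runs = apply_span_filter(runs, cfg)
    if cfg.motif_uniform:
        runs = apply_motif_filter(runs, cfg)
    return runs


def runs_to_bed_rows(
    runs: Iterable[MismatchRun], trace_by_id: dict[str, TraceRead],
    strand_by_id: dict[str, str],
) -> list[BedMismatchRow]:
    rows = []
    for r in runs:
        t = trace_by_id.get(r.trace_id)
        for m in r.mismatches:
            rows.append(
                BedMismatchRow(
                    chrom=m.chrom, start=m.ref_pos, end=m.ref_pos + 1,
                    trace_id=r.trace_id, qual=m.qual if m.qual is not None else 0,
                    strand=strand_by_id.get(r.trace_id, "+"),
                    mismatch_type=m.mismatch_type, trace_pos=m.trace_pos,
                    run_length=r.length,
                    center=t.center if t else "UNKNOWN",
                    organism=t.organism if t else "UNKNOWN",
                    origin=t.origin if t else Origin.UNKNOWN,
                )
            )
    return rows
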