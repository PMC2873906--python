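"""Strict trace placement: seed-and-extend ungapped alignment plus the
accept/reject rules (length >= 400, identity >= 97%, no indels, unique locus).

The internal aligner exists so synthetic cohorts can be placed without an
external aligner; archive-scale alignment is out of scope. Placements from an
external 12-column table go through the same :func:`classify_placement`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .io_formats import ReferenceGenome, TabularAlignment, TraceRead, revcomp

__all__ = [
    "FilterConfig",
    "AlignmentRecord",
    "Placement",
    "PlacementOutcome",
    "build_seed_index",
    "align_trace",
    "classify_placement",
    "place_traces",
]


@dataclass(frozen=True)
class FilterConfig:
    """Acceptance criteria for a trace placement.

    Defaults mirror the strict archive screen: alignments of at least 400 bp
    at 97% identity, seeded with exact 60-mers, no indels, unique locus.
    """

    min_aln_len: int = 400
    min_identity: float = 0.97
    seed_len: int = 60
    allow_indels: bool = False  # always False; the pipeline is ungapped
    require_unique: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if self.seed_len > self.min_aln_len:
            raise ValueError("seed_len must not exceed min_aln_len")
        if self.allow_indels:
            raise ValueError("the placement model is strictly ungapped")


@dataclass(frozen=True)
class AlignmentRecord:
    """An ungapped placement of a trace window on the reference.

    ``trace_start``/``trace_end`` are 0-based half-open in read orientation.
    For minus-strand placements read position ``trace_start + i`` pairs with
    reference position ``ref_end - 1 - i``; for plus strand, ``ref_start + i``.
    """

    trace_id: str
    chrom: str
    ref_start: int
    ref_end: int
    trace_start: int
    trace_end: int
    strand: str
    n_mismatch: int
    has_indel: bool = False

    def __post_init__(self) -> None:
        if not self.has_indel and (
            self.ref_end - self.ref_start != self.trace_end - self.trace_start
        ):
            raise ValueError(
                f"{self.trace_id}: ungapped record with unequal spans "
                f"(ref {self.ref_end - self.ref_start}, "
                f"trace {self.trace_end - self.trace_start})"
            )

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def identity(self) -> float:
        return 1.0 - self.n_mismatch / self.length

    def ref_pos(self, trace_pos: int) -> int:
        """Reference position aligned to a read-orientation trace position."""
        i = trace_pos - self.trace_start
        if not 0 <= i < self.length:
            raise IndexError(f"trace position {trace_pos} outside alignment")
        if self.strand == "+":
            return self.ref_start + i
        return self.ref_end - 1 - i

    @staticmethod
    def from_tabular(t: TabularAlignment) -> "AlignmentRecord":
        return AlignmentRecord(
            trace_id=t.trace_id, chrom=t.chrom,
            ref_start=t.ref_start, ref_end=t.ref_end,
            trace_start=t.trace_start, trace_end=t.trace_end,
            strand=t.strand, n_mismatch=t.n_mismatch, has_indel=t.has_indel,
        )


class PlacementOutcome(str, Enum):
    UNIQUE = "UNIQUE"
    MULTIPLE = "MULTIPLE"
    NONE = "NONE"


@dataclass
class Placement:
    """Outcome of classifying a trace's candidate placements."""

    outcome: PlacementOutcome
    record: AlignmentRecord | None = None
    n_loci: int = 0


SeedIndex = dict[str, list[tuple[str, int]]]


def build_seed_index(reference: ReferenceGenome, seed_len: int = 60) -> SeedIndex:
    """Exact-k-mer index of the reference; seeds containing N are skipped."""
    if seed_len < 8:
        raise ValueError("seed_len must be at least 8")
    index: SeedIndex = {}
    any_indexed = False
    for name, seq in reference.items():
        if len(seq) < seed_len:
            continue
        any_indexed = True
        for pos in range(len(seq) - seed_len + 1):
            kmer = seq[pos : pos + seed_len]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append((name, pos))
    if not any_indexed:
        warnings.warn("reference shorter than seed length; empty seed index")
    return index


def _extend(q: str, ref: str, q_hit: int, diag: int, seed_len: int):
    """Maximal ungapped window around a seed hit on one diagonal.

    Extension stops at sequence ends or at an N in either sequence (N cannot
    be scored as match or mismatch).
    """
    lo_bound = max(0, -diag)
    hi_bound = min(len(q), len(ref) - diag)
    lo = q_hit
    while lo > lo_bound and q[lo - 1] != "N" and ref[lo - 1 + diag] != "N":
        lo -= 1
    hi = q_hit + seed_len
    while hi < hi_bound and q[hi] != "N" and ref[hi + diag] != "N":
        hi += 1
    n_mm = sum(1 for i in range(lo, hi) if q[i] != ref[i + diag])
    return lo, hi, n_mm


def align_trace(
    trace: TraceRead,
    index: SeedIndex,
    reference: ReferenceGenome,
    cfg: FilterConfig = FilterConfig(),
) -> list[AlignmentRecord]:
    """Candidate ungapped placements of a trace on both strands.

    Seeds are probed at half-seed stride (plus the final window) on the
    oriented query; each hit is extended to a maximal window on its diagonal
    and candidates are de-duplicated by (chrom, strand, window).
    """
    k = cfg.seed_len
    n = len(trace.sequence)
    if n < k:
        return []
    stride = max(1, k // 2)
    probe_starts = list(range(0, n - k + 1, stride))
    if probe_starts[-1] != n - k:
        probe_starts.append(n - k)

    out: list[AlignmentRecord] = []
    seen: set[tuple[str, str, int, int]] = set()
    for strand in "+-":
        q = trace.sequence if strand == "+" else revcomp(trace.sequence)
        for qs in probe_starts:
            kmer = q[qs : qs + k]
            if "N" in kmer:
                continue
            for chrom, pos in index.get(kmer, ()):
                diag = pos - qs
                lo, hi, n_mm = _extend(q, reference[chrom], qs, diag, k)
                key = (chrom, strand, lo + diag, hi + diag)
                if key in seen:
                    continue
                seen.add(key)
                if strand == "+":
                    t_start, t_end = lo, hi
                else:
                    t_start, t_end = n - hi, n - lo
                out.append(
                    AlignmentRecord(
                        trace_id=trace.trace_id, chrom=chrom,
                        ref_start=lo + diag, ref_end=hi + diag,
                        trace_start=t_start, trace_end=t_end,
                        strand=strand, n_mismatch=n_mm,
                    )
                )
    return out


def _same_locus(a: AlignmentRecord, b: AlignmentRecord) -> bool:
    """Reciprocal >=50% overlap on the same chrom+strand = one locus.

    Seed hits tile a single placement and must not fake multiplicity.
    """
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    ov = min(a.ref_end, b.ref_end) - max(a.ref_start, b.ref_start)
    return ov >= 0.5 * a.length and ov >= 0.5 * b.length


def classify_placement(
    candidates: Iterable[AlignmentRecord | TabularAlignment],
    cfg: FilterConfig = FilterConfig(),
) -> Placement:
    """Apply length/identity/indel filters, then the unique-locus rule."""
    records = [
        c if isinstance(c, AlignmentRecord) else AlignmentRecord.from_tabular(c)
        for c in candidates
    ]
    passing = [
        r
        for r in records
        if not r.has_indel
        and r.length >= cfg.min_aln_len
        and r.identity >= cfg.min_identity
    ]
    if not passing:
        return Placement(PlacementOutcome.NONE, None, 0)

    # greedy locus grouping; overlapping duplicates at one locus count once
    loci: list[list[AlignmentRecord]] = []
    for r in sorted(passing, key=lambda r: (-r.length, r.n_mismatch)):
        for group in loci:
            if _same_locus(group[0], r):
                group.append(r)
                break
        else:
            loci.append([r])

    best = max(
        (max(g, key=lambda r: (r.identity, r.length)) for g in loci),
        key=lambda r: (r.identity, r.length),
    )
    if len(loci) == 1:
        return Placement(PlacementOutcome.UNIQUE, best, 1)
    if cfg.require_unique:
        return Placement(PlacementOutcome.MULTIPLE, None, len(loci))
    return Placement(PlacementOutcome.MULTIPLE, best, len(loci))


def place_traces(
    traces: Sequence[TraceRead],
    reference: ReferenceGenome,
    cfg: FilterConfig = FilterConfig(),
    index: SeedIndex | None = None,
) -> dict[str, Placement]:
    """Align and classify a cohort; returns per-trace placements."""
    if index is None:
        index = build_seed_index(reference, cfg.seed_len)
    return {
        t.trace_id: classify_placement(align_trace(t, index, reference, cfg), cfg)
        for t in traces
    }
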