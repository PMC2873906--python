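"""Phred-based enriched trace sets and the mismatch spectra.

The high-quality ("editing enriched") set keeps traces carrying a run of at
least three same-type mismatches, of any quality, in which at least two
members reach phred >= 40 and lie >= 100 bp apart on the trace. The
low-quality set mirrors the definition with the predicate inverted
(phred < 10); it characterizes the systematic artifact rather than editing.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence
import warnings

import numpy as np
import pandas as pd

from .io_formats import MISMATCH_TYPES, Origin, TraceRead
from .cluster_scan import Mismatch, MismatchRun

__all__ = [
    "QualityMode",
    "QualitySetConfig",
    "EnrichedTrace",
    "select_enriched",
    "tally_by_type",
    "table2_style",
    "spectrum_by_run_length",
    "spectrum_by_quality",
]

EDITING_TYPES = ("G>A", "C>T", "A>G", "T>C")


class QualityMode(str, Enum):
    HIGH = "HIGH"   # phred >= threshold (editing enriched)
    LOW = "LOW"     # phred < threshold (artifact characterizing)


@dataclass(frozen=True)
class QualitySetConfig:
    run_min: int = 3
    mode: QualityMode = QualityMode.HIGH
    q_threshold: int | None = None   # HIGH default 40, LOW default 10
    min_qualified: int = 2
    min_pair_sep_bp: int = 100

    def __post_init__(self) -> None:
        if self.min_qualified < 2:
            raise ValueError("min_qualified must be >= 2")

    @property
    def threshold(self) -> int:
        if self.q_threshold is not None:
            return self.q_threshold
        return 40 if self.mode is QualityMode.HIGH else 10

    def passes(self, qual: int | None) -> bool:
        if qual is None:
            return False
        if self.mode is QualityMode.HIGH:
            return qual >= self.threshold
        return qual < self.threshold


@dataclass
class EnrichedTrace:
    """A trace admitted to a quality set, typed by its qualifying run.

    Only the predicate-passing mismatches are reported (the BED files carry
    exactly these), but ``run_length`` is the full run's length.
    """

    trace_id: str
    mismatch_type: str
    origin: Origin
    mismatches: list[Mismatch]
    run_length: int


def _qualifies(members: Sequence[Mismatch], cfg: QualitySetConfig) -> list[Mismatch]:
    passing = [m for m in members if cfg.passes(m.qual)]
    if len(passing) < cfg.min_qualified:
        return []
    pos = [m.trace_pos for m in passing]
    if max(pos) - min(pos) < cfg.min_pair_sep_bp:
        return []
    return passing


def select_enriched(
    traces: Sequence[TraceRead],
    runs_by_trace: Mapping[str, Sequence[MismatchRun]],
    cfg: QualitySetConfig = QualitySetConfig(),
) -> list[EnrichedTrace]:
    """Build the quality set from per-trace runs (built with min_run=run_min).

    A trace is counted once per qualifying run type; several qualifying runs
    of the same type contribute a single entry (the one with most passing
    members). Traces without quality scores cannot be assessed and are
    excluded with a warning.
    """
    by_id = {t.trace_id: t for t in traces}
    out: list[EnrichedTrace] = []
    n_noqual = 0
    for trace_id, runs in runs_by_trace.items():
        trace = by_id.get(trace_id)
        if trace is None:
            continue
        if trace.quals is None:
            if runs:
                n_noqual += 1
            continue
        best_by_type: dict[str, EnrichedTrace] = {}
        for run in runs:
            if run.length < cfg.run_min:
                continue
            passing = _qualifies(run.mismatches, cfg)
            if not passing:
                continue
            cur = best_by_type.get(run.mismatch_type)
            if cur is None or len(passing) > len(cur.mismatches):
                best_by_type[run.mismatch_type] = EnrichedTrace(
                    trace_id=trace_id,
                    mismatch_type=run.mismatch_type,
                    origin=trace.origin,
                    mismatches=list(passing),
                    run_length=run.length,
                )
        out.extend(best_by_type[t] for t in sorted(best_by_type))
    if n_noqual:
        warnings.warn(
            f"{n_noqual} traces with runs had no quality scores and were excluded"
        )
    return out


def tally_by_type(
    enriched: Iterable[EnrichedTrace], by_origin: bool = False
) -> pd.DataFrame:
    """Trace counts per mismatch type; optionally an RNA-origin column."""
    counts = {t: 0 for t in MISMATCH_TYPES}
    rna = {t: 0 for t in MISMATCH_TYPES}
    for e in enriched:
        counts[e.mismatch_type] += 1
        if e.origin is Origin.RNA:
            rna[e.mismatch_type] += 1
    df = pd.DataFrame({"count": pd.Series(counts)})
    if by_origin:
        df["rna"] = pd.Series(rna)
    df.index.name = "mismatch_type"
    return df


def table2_style(tally: pd.DataFrame) -> pd.DataFrame:
    """Reshape a 12-type tally into the 4 editing types + "other" row shape.

    "Other" is the largest substitution type outside {G>A, C>T, A>G, T>C}.
    """
    rest = tally.drop(index=list(EDITING_TYPES))
    other_type = rest["count"].idxmax()
    rows = {t: tally.loc[t] for t in EDITING_TYPES}
    rows["other"] = rest.loc[other_type]
    out = pd.DataFrame(rows).T
    out.index.name = "mismatch_type"
    return out.astype(int)


def spectrum_by_run_length(
    runs: Iterable[MismatchRun], max_k: int = 10
) -> pd.DataFrame:
    """Percent of runs of each type among runs of length >= k, k = 1..max_k.

    Each row (k-slice) sums to 100% whenever any run reaches that length.
    """
    lengths: dict[str, list[int]] = {t: [] for t in MISMATCH_TYPES}
    for r in runs:
        lengths[r.mismatch_type].append(r.length)
    data = {}
    for k in range(1, max_k + 1):
        counts = np.array(
            [sum(1 for L in lengths[t] if L >= k) for t in MISMATCH_TYPES],
            dtype=float,
        )
        total = counts.sum()
        data[k] = 100.0 * counts / total if total else counts
    df = pd.DataFrame(data, index=list(MISMATCH_TYPES)).T
    df.index.name = "min_run_length"
    return df


def spectrum_by_quality(
    runs: Iterable[MismatchRun],
    bins: Sequence[int] = (0, 10, 20, 30, 40, 94),
) -> pd.DataFrame:
    """Per-phred-bin substitution-type fractions over run member mismatches.

    Bin edges are closed on the left, open on the right, so a mismatch at
    phred 39 never lands in the [40, ...) bin.
    """
    edges = np.asarray(bins)
    labels = [f"[{edges[i]},{edges[i + 1]})" for i in range(len(edges) - 1)]
    arr = np.zeros((len(labels), len(MISMATCH_TYPES)))
    col = {t: j for j, t in enumerate(MISMATCH_TYPES)}
    for r in runs:
        for m in r.mismatches:
            if m.qual is None:
                continue
            i = int(np.searchsorted(edges, m.qual, side="right")) - 1
            if 0 <= i < len(labels):
                arr[i, col[m.mismatch_type]] += 1
    counts = pd.DataFrame(arr, index=labels, columns=list(MISMATCH_TYPES))
    totals = counts.sum(axis=1)
    frac = counts.div(totals.where(totals > 0, 1.0), axis=0)
    frac.index.name = "phred_bin"
    return frac
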