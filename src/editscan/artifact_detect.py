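"""The systematic dye sub-peak G-to-A basecalling error.

In affected chromatograms every peak is preceded by a small echo of the next
peak; in an AGA or AGG context the tall A peak's sub-peak can overwhelm the
intrinsically low G peak, so the G is called A. Two independent diagnostics:

* the motif signature — clustered G>A mismatches whose centered 3-mers are
  AGA->AAA or AGG->AAG, in read orientation (the artifact is a property of
  the read chemistry, not the genome, so no strand folding is applied);
* the alternate-basecall offset test — a basecaller's second-best calls for
  an affected trace reproduce the primary calls shifted by one position, so a
  long single-offset agreement block between the two sequences betrays the
  sub-peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .cluster_scan import MismatchRun
from .io_formats import TraceRead

__all__ = [
    "AlternateCalls",
    "ArtifactVerdict",
    "ARTIFACT_MOTIFS",
    "motif_artifact_flag",
    "offset_artifact_test",
    "simulate_subpeak_trace",
]

#: (reference 3-mer, trace 3-mer) pairs diagnostic of the sub-peak error.
ARTIFACT_MOTIFS = frozenset({("AGA", "AAA"), ("AGG", "AAG")})


@dataclass(frozen=True)
class AlternateCalls:
    """Primary and second-best base call per position of one trace."""

    trace_id: str
    primary_seq: str
    alternate_seq: str

    def __post_init__(self) -> None:
        if len(self.primary_seq) != len(self.alternate_seq):
            raise ValueError(
                f"{self.trace_id}: primary and alternate call sequences differ "
                "in length"
            )


@dataclass(frozen=True)
class ArtifactVerdict:
    motif_flag: bool
    offset_flag: bool
    offset: int | None = None
    evidence: int = 0

    def __post_init__(self) -> None:
        if self.offset_flag and abs(self.offset or 0) != 1:
            raise ValueError("an offset flag requires offset +1 or -1")


def motif_artifact_flag(run: MismatchRun) -> bool:
    """True iff a G>A run carries only the two artifact motif signatures.

    Every member's (reference, trace) centered 3-mer pair must be AGA->AAA or
    AGG->AAG; real artifact traces freely mix the two contexts. For a
    motif-uniform run this reduces to membership of its single motif pair.
    """
    if run.mismatch_type != "G>A":
        return False
    return all(
        (m.ref_motif, m.trace_motif) in ARTIFACT_MOTIFS for m in run.mismatches
    )


def _longest_shifted_block(alt: str, prim: str, d: int) -> int:
    """Longest block with alt[i] == prim[i+d] over valid i."""
    if d >= 0:
        a, b = alt[: len(alt) - d], prim[d:]
    else:
        a, b = alt[-d:], prim[: len(prim) + d]
    best = cur = 0
    for x, y in zip(a, b):
        if x == y:
            cur += 1
            if cur > best:
                best = cur
        else:
            cur = 0
    return best


def offset_artifact_test(calls: AlternateCalls, min_block: int = 50) -> ArtifactVerdict:
    """Flag a trace whose alternate calls track the primary calls at +-1.

    ``min_block`` is set so that unrelated 400-mers (expected longest chance
    agreement ~ log4 of the length) essentially never flag, while a genuine
    sub-peak shift always does.
    """
    n = len(calls.primary_seq)
    if n < min_block:
        warnings.warn(
            f"{calls.trace_id}: sequences shorter than min_block={min_block}; "
            "offset test not informative"
        )
        return ArtifactVerdict(motif_flag=False, offset_flag=False, evidence=0)
    best_d, best = None, 0
    for d in (-1, 1):
        block = _longest_shifted_block(calls.alternate_seq, calls.primary_seq, d)
        if block > best:
            best_d, best = d, block
    if best >= min_block:
        return ArtifactVerdict(
            motif_flag=False, offset_flag=True, offset=best_d, evidence=best
        )
    return ArtifactVerdict(motif_flag=False, offset_flag=False, evidence=best)


def simulate_subpeak_trace(
    reference_window: str,
    rng: np.random.Generator,
    miscall_prob: float = 0.9,
    qual_range: tuple[int, int] = (15, 35),
    base_qual: int = 45,
    trace_id: str = "subpeak",
    qual_sampler: Callable[[np.random.Generator], int] | None = None,
    max_miscalls: int | None = None,
) -> tuple[TraceRead, AlternateCalls, list[int]]:
    """Generate a sub-peak artifact read over a reference window.

    Each G centered in an AGA or AGG context is mis-called A independently
    with ``miscall_prob``; mis-called positions get a quality drawn from
    ``qual_range`` (or from ``qual_sampler``), other positions ``base_qual``.
    The alternate call sequence is the primary shifted by +1 — the echo of
    the following peak — so the offset test fires on these reads.

    ``max_miscalls`` caps the mis-call count (a uniform subsample is kept):
    cohort generation uses it to model the observable artifact population,
    whose members pass the identity screen by construction.

    Returns the read, its alternate calls, and the mis-called positions.
    """
    if len(reference_window) < 400:
        raise ValueError("window length must be >= 400")
    bases = list(reference_window)
    quals = [base_qual] * len(bases)
    sites: list[int] = []
    for i in range(1, len(bases) - 1):
        if (
            reference_window[i] == "G"
            and reference_window[i - 1] == "A"
            and reference_window[i + 1] in "AG"
        ):
            if rng.random() < miscall_prob:
                sites.append(i)
    if max_miscalls is not None and len(sites) > max_miscalls:
        keep = rng.choice(len(sites), size=max_miscalls, replace=False)
        sites = [sites[j] for j in sorted(keep)]
    for i in sites:
        bases[i] = "A"
        if qual_sampler is not None:
            quals[i] = int(qual_sampler(rng))
        else:
            quals[i] = int(rng.integers(qual_range[0], qual_range[1] + 1))
    primary = "".join(bases)
    alternate = primary[1:] + primary[-1]
    trace = TraceRead(trace_id=trace_id, sequence=primary, quals=quals)
    return trace, AlternateCalls(trace_id, primary, alternate), sites
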