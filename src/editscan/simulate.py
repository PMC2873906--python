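"""Seeded generator of reference + trace cohorts with planted signals.

The generator emulates the data the scanner was built for: capillary-length
reads (400-900 bp) with phred-calibrated substitution errors, a planted
near-identical repeat family (the retroelement stand-in), A-to-I editing
clusters injected into RNA-origin traces in transcript sense (so roughly
half surface as T>C runs on minus-strand placements), APOBEC-style G>A
clusters in repeat-overlapping DNA traces with the GG/GA dinucleotide
preference, and dye sub-peak artifact traces with shifted alternate calls.
Every planted difference is recorded in a truth table keyed by
(trace_id, trace_pos) so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .artifact_detect import AlternateCalls, simulate_subpeak_trace
from .io_formats import (
    IntervalSet,
    Origin,
    ReferenceGenome,
    TraceRead,
    revcomp,
    write_fasta,
    write_metadata,
    write_qual,
)

__all__ = [
    "QualityProfile",
    "EditingConfig",
    "DnaEditingConfig",
    "ArtifactConfig",
    "SimConfig",
    "SimTruth",
    "TraceTruth",
    "SiteTruth",
    "make_reference",
    "make_traces",
    "simulate_cohort",
    "write_truth",
]

_BASES = "ACGT"
_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class QualityProfile:
    """Flat high-quality read with a linearly degraded tail.

    Defaults model a good capillary run: phred 45 over the first 80% of the
    read, decaying linearly to phred 25 at the final base.
    """

    base_qual: int = 45
    tail_start_frac: float = 0.8
    tail_end_qual: int = 25

    def quals(self, length: int) -> np.ndarray:
        q = np.full(length, self.base_qual, dtype=int)
        tail_start = int(self.tail_start_frac * length)
        n_tail = length - tail_start
        if n_tail > 1:
            q[tail_start:] = np.round(
                np.linspace(self.base_qual, self.tail_end_qual, n_tail)
            ).astype(int)
        return q


@dataclass(frozen=True)
class EditingConfig:
    """A-to-I editing clusters planted in RNA traces (transcript sense A>G)."""

    fraction: float = 0.5          # of RNA-origin traces
    sites_per_cluster: int = 5     # >= 3
    cluster_span: tuple[int, int] = (130, 220)   # window width, bp
    min_planted_span: int = 110    # first-to-last site distance floor
    qual_range: tuple[int, int] = (40, 50)
    upstream_g_weight: float = 0.25  # 4:1 avoidance of a 5' G (ADAR signature)


@dataclass(frozen=True)
class DnaEditingConfig:
    """APOBEC-style G>A clusters in repeat-overlapping DNA traces."""

    fraction: float = 0.5          # of repeat-overlapping DNA traces
    sites_per_cluster: int = 5
    cluster_span: tuple[int, int] = (130, 220)
    min_planted_span: int = 110
    qual_range: tuple[int, int] = (35, 50)
    dinucleotide_weight: float = 4.0  # preference for GG / GA contexts


def _skewed_artifact_qual(rng: np.random.Generator, qual_max: int = 34) -> int:
    # right-skewed toward low phred (median ~7): the sub-peak usually
    # dominates the true peak only marginally, so confidence is mostly low
    return 3 + int((qual_max - 2) * rng.random() ** 3)


@dataclass(frozen=True)
class ArtifactConfig:
    """Dye sub-peak traces: AGA/AGG G mis-called A, low-to-moderate quality.

    The mis-call probability keeps affected reads near a 1.7% mismatch rate:
    archive artifact traces by construction passed the 97%-identity screen,
    so the emulation must survive it too.
    """

    fraction: float = 0.2          # of all traces
    miscall_prob: float = 0.55
    max_mismatch_frac: float = 0.025  # cap; observable artifacts pass 97% id
    qual_max: int = 34             # never reaches the phred-40 high-set bar


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    ref_len: int = 100_000
    n_repeat_copies: int = 6
    repeat_len: int = 300
    repeat_divergence: float = 0.01
    n_traces: int = 500
    trace_len_range: tuple[int, int] = (400, 900)
    rna_fraction: float = 0.5
    quality: QualityProfile = field(default_factory=QualityProfile)
    editing: EditingConfig = field(default_factory=EditingConfig)
    dna_editing: DnaEditingConfig = field(default_factory=DnaEditingConfig)
    artifact: ArtifactConfig = field(default_factory=ArtifactConfig)
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        for f in (self.rna_fraction, self.editing.fraction,
                  self.dna_editing.fraction, self.artifact.fraction):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.editing.sites_per_cluster < 3:
            raise ValueError("editing clusters carry at least 3 sites")

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        raw = dict(raw)
        for key, sub in (
            ("quality", QualityProfile), ("editing", EditingConfig),
            ("dna_editing", DnaEditingConfig), ("artifact", ArtifactConfig),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**{
                    k: tuple(v) if isinstance(v, (list, tuple)) else v
                    for k, v in raw[key].items()
                })
        if isinstance(raw.get("trace_len_range"), list):
            raw["trace_len_range"] = tuple(raw["trace_len_range"])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TraceTruth:
    trace_id: str
    label: str                      # edited_rna | edited_dna | artifact | clean
    chrom: str
    ref_start: int
    ref_end: int
    strand: str
    origin: str


@dataclass
class SiteTruth:
    trace_id: str
    trace_pos: int
    ref_pos: int
    planted_type: str               # read orientation, e.g. "A>G"
    qual: int
    kind: str                       # rna_edit | dna_edit | artifact


@dataclass
class SimTruth:
    traces: dict[str, TraceTruth] = field(default_factory=dict)
    sites: list[SiteTruth] = field(default_factory=list)

    def labelled(self, label: str) -> list[str]:
        return [t.trace_id for t in self.traces.values() if t.label == label]


def make_reference(cfg: SimConfig) -> tuple[ReferenceGenome, IntervalSet]:
    """Uniform background with a planted near-identical repeat family."""
    if cfg.ref_len < 10 * cfg.repeat_len:
        raise ValueError("ref_len must be at least 10x repeat_len")
    rng = np.random.default_rng(cfg.seed)
    arr = rng.integers(0, 4, cfg.ref_len)
    repeats = IntervalSet()
    if cfg.n_repeat_copies > 0:
        motif = rng.integers(0, 4, cfg.repeat_len)
        slot = cfg.ref_len // (cfg.n_repeat_copies + 1)
        for i in range(cfg.n_repeat_copies):
            start = slot * (i + 1)
            copy = motif.copy()
            mut = rng.random(cfg.repeat_len) < cfg.repeat_divergence
            copy[mut] = (copy[mut] + rng.integers(1, 4, mut.sum())) % 4
            arr[start : start + cfg.repeat_len] = copy
            repeats.add(cfg.chrom, start, start + cfg.repeat_len, f"rep{i}")
    seq = _LUT[arr].tobytes().decode()
    return ReferenceGenome({cfg.chrom: seq}), repeats


def _pick_cluster(
    window: str,
    rng: np.random.Generator,
    target_base: str,
    k: int,
    span_range: tuple[int, int],
    min_span: int,
    weight_fn,
    n_attempts: int = 30,
) -> list[int] | None:
    """Choose k window-relative positions of ``target_base`` spanning
    >= min_span, weighted by sequence context; None if no placement found."""
    L = len(window)
    for _ in range(n_attempts):
        w = int(rng.integers(span_range[0], min(span_range[1], L - 4) + 1))
        ws = int(rng.integers(0, L - w))
        cands = [
            p for p in range(max(1, ws), min(L - 1, ws + w))
            if window[p] == target_base
        ]
        if len(cands) < k or cands[-1] - cands[0] < min_span:
            continue

        def pick(pool):
            wts = np.array([weight_fn(p) for p in pool], dtype=float)
            return int(rng.choice(pool, p=wts / wts.sum()))

        # anchor the cluster ends in the outer quartiles (context-weighted,
        # so the planted sequence signature holds at every site)
        quart = (cands[-1] - cands[0]) // 4
        lo = pick([p for p in cands if p - cands[0] <= quart])
        hi = pick([p for p in cands if cands[-1] - p <= quart])
        if hi - lo < min_span:
            continue
        middle = [p for p in cands if lo < p < hi]
        if len(middle) < k - 2:
            continue
        weights = np.array([weight_fn(p) for p in middle], dtype=float)
        chosen = rng.choice(
            middle, size=k - 2, replace=False, p=weights / weights.sum()
        )
        return sorted({lo, hi, *(int(c) for c in chosen)})
    return None


def _apply_background_errors(
    bases: list[str], quals: np.ndarray, protected: set[int],
    rng: np.random.Generator,
) -> list[int]:
    """Phred-calibrated substitution errors; returns the erred positions."""
    err_p = 10.0 ** (-quals / 10.0)
    hits = np.flatnonzero(rng.random(len(bases)) < err_p)
    erred = []
    for i in hits:
        i = int(i)
        if i in protected:
            continue
        alts = [b for b in _BASES if b != bases[i]]
        bases[i] = alts[int(rng.integers(0, 3))]
        erred.append(i)
    return erred


def make_traces(
    cfg: SimConfig,
    reference: ReferenceGenome,
    repeats: IntervalSet | None = None,
) -> tuple[list[TraceRead], SimTruth, dict[str, AlternateCalls]]:
    """Sample a trace cohort with planted editing/artifact signals + truth."""
    lo_len, hi_len = cfg.trace_len_range
    if cfg.editing.cluster_span[0] > lo_len - 4:
        raise ValueError("editing cluster span exceeds the shortest trace")
    if repeats is None:
        repeats = IntervalSet()
    rng = np.random.default_rng(cfg.seed + 1)
    ref_seq = reference[cfg.chrom]
    ref_len = len(ref_seq)
    traces: list[TraceRead] = []
    truth = SimTruth()
    alt_calls: dict[str, AlternateCalls] = {}

    for idx in range(cfg.n_traces):
        trace_id = f"sim{idx:05d}"
        L = int(rng.integers(lo_len, hi_len + 1))
        start = int(rng.integers(0, ref_len - L + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        origin = Origin.RNA if rng.random() < cfg.rna_fraction else Origin.DNA
        window = ref_seq[start : start + L]   # plus-sense reference window

        in_repeat = repeats.overlaps_interval(cfg.chrom, start, start + L)
        if rng.random() < cfg.artifact.fraction:
            label = "artifact"
        elif origin is Origin.RNA and rng.random() < cfg.editing.fraction:
            label = "edited_rna"
        elif (
            origin is Origin.DNA
            and in_repeat
            and rng.random() < cfg.dna_editing.fraction
        ):
            label = "edited_dna"
        else:
            label = "clean"

        quals = cfg.quality.quals(L)
        sites: list[SiteTruth] = []

        if label == "artifact":
            read0 = window if strand == "+" else revcomp(window)
            art, _, art_sites = simulate_subpeak_trace(
                read0, rng,
                miscall_prob=cfg.artifact.miscall_prob,
                qual_sampler=lambda r: _skewed_artifact_qual(
                    r, cfg.artifact.qual_max
                ),
                trace_id=trace_id,
                max_miscalls=int(cfg.artifact.max_mismatch_frac * L),
            )
            bases = list(art.sequence)
            for t in art_sites:
                quals[t] = art.quals[t]
                rp = start + t if strand == "+" else start + L - 1 - t
                sites.append(
                    SiteTruth(trace_id, t, rp, "G>A", int(quals[t]), "artifact")
                )
            if not sites:
                label = "clean"   # window happened to carry no AGA/AGG miscall
        else:
            edited = list(window)  # transcript/plus sense
            if label in ("edited_rna", "edited_dna"):
                if label == "edited_rna":
                    e = cfg.editing
                    target, new_base, kind = "A", "G", "rna_edit"
                    weight_fn = lambda p: (
                        e.upstream_g_weight if window[p - 1] == "G" else 1.0
                    )
                else:
                    e = cfg.dna_editing
                    target, new_base, kind = "G", "A", "dna_edit"
                    weight_fn = lambda p: (
                        e.dinucleotide_weight if window[p + 1] in "GA" else 1.0
                    )
                picked = _pick_cluster(
                    window, rng, target, e.sites_per_cluster,
                    e.cluster_span, e.min_planted_span, weight_fn,
                )
                if picked is None:
                    label = "clean"
                else:
                    for p in picked:
                        edited[p] = new_base
                        t = p if strand == "+" else L - 1 - p
                        quals[t] = int(
                            rng.integers(e.qual_range[0], e.qual_range[1] + 1)
                        )
                        if kind == "rna_edit":
                            ptype = "A>G" if strand == "+" else "T>C"
                        else:
                            ptype = "G>A" if strand == "+" else "C>T"
                        sites.append(
                            SiteTruth(trace_id, t, start + p, ptype,
                                      int(quals[t]), kind)
                        )
            plus_read = "".join(edited)
            bases = list(plus_read if strand == "+" else revcomp(plus_read))

        protected = {s.trace_pos for s in sites}
        _apply_background_errors(bases, quals, protected, rng)

        primary = "".join(bases)
        if label == "artifact":
            alt_calls[trace_id] = AlternateCalls(
                trace_id, primary, primary[1:] + primary[-1]
            )
        trace = TraceRead(
            trace_id=trace_id, sequence=primary, quals=[int(q) for q in quals],
            origin=origin, center="SIMCENTER", organism="simulans",
        )
        traces.append(trace)
        truth.traces[trace_id] = TraceTruth(
            trace_id, label, cfg.chrom, start, start + L, strand, origin.value
        )
        truth.sites.extend(sites)

    return traces, truth, alt_calls


def simulate_cohort(cfg: SimConfig):
    """Reference, repeats, traces, truth, and artifact alternate calls."""
    reference, repeats = make_reference(cfg)
    traces, truth, alt_calls = make_traces(cfg, reference, repeats)
    return reference, repeats, traces, truth, alt_calls


def write_truth(truth: SimTruth, path) -> None:
    """Tab-separated truth tables: <path> per-site, <path>.labels per-trace."""
    import pandas as pd

    pd.DataFrame([asdict(s) for s in truth.sites]).to_csv(
        path, sep="\t", index=False
    )
    pd.DataFrame([asdict(t) for t in truth.traces.values()]).to_csv(
        str(path) + ".labels", sep="\t", index=False
    )


def write_cohort(cfg: SimConfig, out_dir) -> dict[str, str]:
    """Materialize a cohort to disk (reference.fa, traces.fa, traces.qual,
    meta.tsv, truth.tsv, repeats.bed, alt_calls.fa); returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference, repeats, traces, truth, alt_calls = simulate_cohort(cfg)
    paths = {
        "reference": str(out / "reference.fa"),
        "traces": str(out / "traces.fa"),
        "quals": str(out / "traces.qual"),
        "meta": str(out / "meta.tsv"),
        "truth": str(out / "truth.tsv"),
        "repeats": str(out / "repeats.bed"),
        "alt_calls": str(out / "alt_calls.fa"),
    }
    write_fasta(reference, paths["reference"])
    write_fasta(traces, paths["traces"])
    write_qual(traces, paths["quals"])
    write_metadata(traces, paths["meta"])
    write_truth(truth, paths["truth"])
    with open(paths["repeats"], "w") as fh:
        for chrom, s, e, label in repeats.intervals():
            fh.write(f"{chrom}\t{s}\t{e}\t{label}\n")
    with open(paths["alt_calls"], "w") as fh:
        for ac in alt_calls.values():
            fh.write(f">{ac.trace_id}\n{ac.alternate_seq}\n")
    return paths
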