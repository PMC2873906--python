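"""Mismatch enumeration, run structure, and the span/motif filters."""

from collections import namedtuple
from itertools import groupby, product

import pytest
from hypothesis import given, strategies as st

from editscan.cluster_scan import (
    Mismatch,
    MismatchRun,
    ScanConfig,
    apply_motif_filter,
    apply_span_filter,
    enumerate_mismatches,
    find_runs,
)
from editscan.io_formats import ReferenceGenome, TraceRead, revcomp
from editscan.placement import AlignmentRecord, PlacementOutcome

MM = namedtuple("MM", ["mismatch_type", "trace_pos"])


from helpers import mk_mismatch  # noqa: E402


class TestEnumerate:
    def _ref_and_trace(self, ref_seq, trace_seq, strand="+"):
        ref = ReferenceGenome({"chr1": ref_seq})
        trace = TraceRead("t", trace_seq)
        aln = AlignmentRecord(
            trace_id="t", chrom="chr1", ref_start=0, ref_end=len(ref_seq),
            trace_start=0, trace_end=len(trace_seq), strand=strand, n_mismatch=0,
        )
        return ref, trace, aln

    def test_perfect_placement_is_empty(self):
        ref, trace, aln = self._ref_and_trace("ACGTACGT", "ACGTACGT")
        assert enumerate_mismatches(aln, ref, trace) == []

    def test_minus_strand_complementation_rule(self):
        # reference CCCCCCCC; read is revcomp-based: all G in read orientation.
        # A read A where the reference implies G reports as G>A.
        ref = ReferenceGenome({"chr1": "CCCCCCCC"})
        read = "GGGAGGGG"
        trace = TraceRead("t", read)
        aln = AlignmentRecord(
            trace_id="t", chrom="chr1", ref_start=0, ref_end=8,
            trace_start=0, trace_end=8, strand="-", n_mismatch=1,
        )
        (m,) = enumerate_mismatches(aln, ref, trace)
        assert m.mismatch_type == "G>A"
        assert m.trace_pos == 3 and m.ref_pos == 4

    def test_n_columns_are_skipped(self):
        ref, trace, aln = self._ref_and_trace("ACGTACGT", "ACGTNCGA")
        mms = enumerate_mismatches(aln, ref, trace)
        assert [(m.trace_pos, m.mismatch_type) for m in mms] == [(7, "T>A")]

    def test_coordinates_outside_reference_error(self):
        ref = ReferenceGenome({"chr1": "ACGT"})
        trace = TraceRead("t", "ACGTACGT")
        aln = AlignmentRecord(
            trace_id="t", chrom="chr1", ref_start=0, ref_end=8,
            trace_start=0, trace_end=8, strand="+", n_mismatch=0,
        )
        with pytest.raises(ValueError, match="corrupt"):
            enumerate_mismatches(aln, ref, trace)

    def test_brute_force_column_walker_agrees_on_cohort(self, cohort, cohort_scan):
        """Independent per-column recount over 200 simulated placements."""
        reference = cohort["reference"]
        by_id = {t.trace_id: t for t in cohort["traces"]}
        checked = 0
        for tid, pl in cohort_scan["placements"].items():
            if pl.outcome is not PlacementOutcome.UNIQUE or checked >= 200:
                continue
            rec = pl.record
            mms = enumerate_mismatches(rec, reference, by_id[tid])
            # oracle: orient the trace and walk the two strings
            ref_window = reference[rec.chrom][rec.ref_start : rec.ref_end]
            read = by_id[tid].sequence[rec.trace_start : rec.trace_end]
            oriented = read if rec.strand == "+" else revcomp(read)
            expected = sum(
                1 for a, b in zip(oriented, ref_window)
                if a != b and a != "N" and b != "N"
            )
            assert len(mms) == expected
            checked += 1
        assert checked == 200


class TestFindRuns:
    def _runs(self, types, min_run=1):
        mms = [MM(t, i * 10) for i, t in enumerate(types)]
        return find_runs(mms, ScanConfig(min_run=min_run, min_span_bp=0))

    def test_definition_example(self):
        runs = self._runs(["G>A", "G>A", "G>A", "C>T"], min_run=3)
        assert [(r.mismatch_type, r.length) for r in runs] == [("G>A", 3)]

    def test_interrupted_blocks(self):
        runs = self._runs(["G>A", "G>A", "C>T", "G>A", "G>A", "G>A"], min_run=3)
        assert [(r.mismatch_type, r.length) for r in runs] == [("G>A", 3)]

    def test_span_arithmetic(self):
        mms = [MM("G>A", p) for p in (10, 70, 120, 200, 250)]
        (run,) = find_runs(mms, ScanConfig(min_run=5, min_span_bp=0))
        assert run.length == 5 and run.span_bp == 240

    def test_exhaustive_small_sequences_vs_sublist_oracle(self):
        """All 4-type sequences up to length 6: every maximal uniform
        contiguous sublist, and nothing else, is reported."""
        types = ["G>A", "C>T", "A>G", "T>C"]
        cfg = ScanConfig(min_run=1, min_span_bp=0)
        for n in range(1, 7):
            for seq in product(types, repeat=n):
                runs = find_runs([MM(t, i) for i, t in enumerate(seq)], cfg)
                oracle = [
                    (i, j)
                    for i in range(n)
                    for j in range(i, n)
                    if len(set(seq[i : j + 1])) == 1
                    and (i == 0 or seq[i - 1] != seq[i])
                    and (j == n - 1 or seq[j + 1] != seq[j])
                ]
                assert [
                    (r.mismatches[0].trace_pos, r.mismatches[-1].trace_pos)
                    for r in runs
                ] == oracle

    @given(st.lists(st.sampled_from(["G>A", "C>T", "A>G", "T>C"]), max_size=40))
    def test_run_partition_property(self, types):
        """At min_run=1 every mismatch belongs to exactly one maximal run."""
        mms = [MM(t, i * 3) for i, t in enumerate(types)]
        runs = find_runs(mms, ScanConfig(min_run=1, min_span_bp=0))
        members = [m for r in runs for m in r.mismatches]
        assert sorted(m.trace_pos for m in members) == [m.trace_pos for m in mms]
        for r in runs:
            assert all(m.mismatch_type == r.mismatch_type for m in r.mismatches)

    @given(st.lists(st.sampled_from(list("ABCD")), min_size=1, max_size=30),
           st.permutations(list("ABCD")))
    def test_relabeling_equivariance(self, labels, perm):
        """Run structure depends only on the label pattern, not label names."""
        mapping = dict(zip("ABCD", perm))
        cfg = ScanConfig(min_run=1, min_span_bp=0)
        a = find_runs([MM(t, i) for i, t in enumerate(labels)], cfg)
        b = find_runs(
            [MM(mapping[t], i) for i, t in enumerate(labels)], cfg
        )
        assert [(len(r.mismatches), r.mismatches[0].trace_pos) for r in a] == [
            (len(r.mismatches), r.mismatches[0].trace_pos) for r in b
        ]


class TestSpanFilter:
    def test_boundary(self):
        cfg = ScanConfig(min_run=2, min_span_bp=100)
        short = MismatchRun("t", "G>A", [mk_mismatch("G>A", 10),
                                        mk_mismatch("G>A", 109)])
        exact = MismatchRun("t", "G>A", [mk_mismatch("G>A", 10),
                                        mk_mismatch("G>A", 110)])
        assert apply_span_filter([short, exact], cfg) == [exact]

    def test_idempotence(self):
        cfg = ScanConfig(min_run=2, min_span_bp=100)
        runs = [
            MismatchRun("t", "G>A", [mk_mismatch("G>A", 0),
                                     mk_mismatch("G>A", d)])
            for d in (50, 100, 150, 240)
        ]
        once = apply_span_filter(runs, cfg)
        assert apply_span_filter(once, cfg) == once


class TestMotifFilter:
    def _run(self, motifs, ref_motif="AGA"):
        mms = [
            mk_mismatch("G>A", 10 * i, trace_motif=m, ref_motif=ref_motif)
            for i, m in enumerate(motifs)
        ]
        return MismatchRun("t", "G>A", mms)

    def test_uniform_kept(self):
        run = self._run(["AAA", "AAA", "AAA"])
        assert apply_motif_filter([run]) == [run]

    def test_mixed_dropped(self):
        assert apply_motif_filter([self._run(["AAA", "AAA", "AAG"])]) == []

    def test_n_context_dropped_whole(self):
        assert apply_motif_filter([self._run(["AAA", "ANA", "AAA"])]) == []

    def test_edge_mismatch_counts_as_n_context(self):
        # position 0 has no full 3-mer: enumeration flags it NNN
        ref = ReferenceGenome({"chr1": "GCGTACGTAC"})
        trace = TraceRead("t", "ACGTACGTAC")
        aln = AlignmentRecord(
            trace_id="t", chrom="chr1", ref_start=0, ref_end=10,
            trace_start=0, trace_end=10, strand="+", n_mismatch=1,
        )
        (m,) = enumerate_mismatches(aln, ref, trace)
        assert m.trace_pos == 0 and m.n_context


def test_complement_symmetry_on_cohort(cohort, cohort_scan):
    """Reverse-complementing the read (flipping placement strand) yields the
    complementary mismatch types with identical run structure."""
    reference = cohort["reference"]
    by_id = {t.trace_id: t for t in cohort["traces"]}
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    cfg = ScanConfig(min_run=1, min_span_bp=0)
    checked = 0
    for tid, pl in cohort_scan["placements"].items():
        if pl.outcome is not PlacementOutcome.UNIQUE or checked >= 50:
            continue
        rec = pl.record
        trace = by_id[tid]
        mms = enumerate_mismatches(rec, reference, trace)
        L = len(trace.sequence)
        flipped = AlignmentRecord(
            trace_id=tid, chrom=rec.chrom, ref_start=rec.ref_start,
            ref_end=rec.ref_end, trace_start=L - rec.trace_end,
            trace_end=L - rec.trace_start,
            strand="-" if rec.strand == "+" else "+",
            n_mismatch=rec.n_mismatch,
        )
        rc_trace = TraceRead(tid, revcomp(trace.sequence))
        mms_rc = enumerate_mismatches(flipped, reference, rc_trace)
        fwd = [
            f"{comp[m.ref_base]}>{comp[m.trace_base]}" for m in reversed(mms)
        ]
        assert [m.mismatch_type for m in mms_rc] == fwd
        runs_a = find_runs(mms, cfg)
        runs_b = find_runs(mms_rc, cfg)
        assert sorted(r.length for r in runs_a) == sorted(r.length for r in runs_b)
        checked += 1
    assert checked == 50
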