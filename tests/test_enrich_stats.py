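"""Exact tests, context profiles, overlap enrichment, and rate estimates."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from editscan.enrich_stats import (
    ContextProfile,
    ContingencyTable,
    GenotypeMatrix,
    editing_rate,
    editing_sense_strand,
    editing_type_fraction,
    fisher_exact_two_sided,
    interval_overlap_enrichment,
    monomorphic_reference_fraction,
    unique_covered_bp,
    upstream_context_profile,
)
from editscan.io_formats import IntervalSet, ReferenceGenome
from editscan.placement import AlignmentRecord, PlacementOutcome


class TestFisher:
    def test_equal_rows_give_p_one(self):
        assert fisher_exact_two_sided([[12, 7], [12, 7]]) == 1.0

    def test_zero_margin_gives_p_one(self):
        assert fisher_exact_two_sided([[0, 0], [5, 9]]) == 1.0
        assert fisher_exact_two_sided([[0, 5], [0, 9]]) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided([[-1, 2], [3, 4]])

    @given(
        st.tuples(*(st.integers(0, 40) for _ in range(4))).filter(
            lambda t: sum(t) > 0
        )
    )
    def test_symmetry_invariances(self, cells):
        a, b, c, d = cells
        p = fisher_exact_two_sided([[a, b], [c, d]])
        assert p == pytest.approx(fisher_exact_two_sided([[c, d], [a, b]]))
        assert p == pytest.approx(fisher_exact_two_sided([[b, a], [d, c]]))
        assert p == pytest.approx(fisher_exact_two_sided([[a, c], [b, d]]))

    @given(
        st.tuples(*(st.integers(0, 500) for _ in range(4))).filter(
            lambda t: sum(t) > 0
        )
    )
    def test_agrees_with_scipy(self, cells):
        a, b, c, d = cells
        ours = fisher_exact_two_sided([[a, b], [c, d]])
        theirs = scipy_fisher([[a, b], [c, d]]).pvalue
        assert ours == pytest.approx(theirs, rel=1e-8, abs=1e-300)

    def test_large_count_stability(self):
        # entries ~1e5: log-space evaluation must stay finite and in [0, 1]
        p = fisher_exact_two_sided([[91_120, 79_401], [91_000, 79_600]])
        assert 0.0 < p <= 1.0


class TestContext:
    def test_sense_strand_mapping(self):
        assert editing_sense_strand("A>G", "+") == "+"
        assert editing_sense_strand("A>G", "-") == "-"
        assert editing_sense_strand("T>C", "+") == "-"
        assert editing_sense_strand("T>C", "-") == "+"
        with pytest.raises(ValueError):
            editing_sense_strand("G>A", "+")

    def test_minus_sense_neighbor_is_complement_of_downstream(self):
        #            0123456
        ref = ReferenceGenome({"chr1": "AATACGT"})
        # minus-sense site at 3: neighbor = complement(ref[4]) = complement(C)=G
        prof = upstream_context_profile([("chr1", 3, "-")], ref)
        assert prof.counts["G"] == 1 and prof.total == 1

    def test_plus_sense_neighbor_is_upstream_base(self):
        ref = ReferenceGenome({"chr1": "GATACGT"})
        prof = upstream_context_profile([("chr1", 1, "+")], ref)
        assert prof.counts["G"] == 1

    def test_contig_edge_excluded_with_warning(self):
        ref = ReferenceGenome({"chr1": "ACGT"})
        with pytest.warns(UserWarning, match="edge"):
            prof = upstream_context_profile([("chr1", 0, "+")], ref)
        assert prof.total == 0 and prof.n_excluded == 1

    def test_fractions_sum_to_one(self):
        prof = ContextProfile.from_counts({"A": 5, "C": 3, "G": 1, "T": 11})
        assert sum(prof.fractions.values()) == pytest.approx(1.0)

    def test_orientation_rule_guards_g_depletion(self, cohort, cohort_scan):
        """Treating T>C sites as if read-sense (deliberately wrong) erases the
        planted upstream-G depletion signal."""
        reference = cohort["reference"]
        truth = cohort["truth"]
        placements = cohort_scan["placements"]
        sites_ok, sites_bad = [], []
        for s in truth.sites:
            if s.kind != "rna_edit":
                continue
            pl = placements[s.trace_id]
            if pl.outcome is not PlacementOutcome.UNIQUE:
                continue
            strand = pl.record.strand
            sites_ok.append(
                ("chrS", s.ref_pos, editing_sense_strand(s.planted_type, strand))
            )
            sites_bad.append(("chrS", s.ref_pos, strand))
        prof_ok = upstream_context_profile(sites_ok, reference)
        prof_bad = upstream_context_profile(sites_bad, reference)
        # 4:1 avoidance => ~7-8% G upstream on the correct orientation;
        # folding by read strand scrambles the minus-sense half back to ~25%
        assert prof_ok.fraction("G") < 0.15
        assert prof_ok.fraction("G") < prof_bad.fraction("G") - 0.05


class TestOverlap:
    def _intervals(self):
        ivs = IntervalSet()
        ivs.add("chr1", 0, 100, "alu")
        return ivs

    def test_nine_of_ten_closed_form(self):
        sites = [("chr1", p) for p in range(10, 100, 10)] + [("chr1", 500)]
        frac, p = interval_overlap_enrichment(sites, self._intervals(), 0.1)
        assert frac == 0.9
        closed = sum(
            math.comb(10, k) * 0.1**k * 0.9 ** (10 - k) for k in range(9, 11)
        )
        assert p == pytest.approx(closed, rel=1e-9)

    def test_no_overlap_gives_p_one(self):
        sites = [("chr1", 500 + i) for i in range(5)]
        frac, p = interval_overlap_enrichment(sites, self._intervals(), 0.1)
        assert frac == 0.0 and p == pytest.approx(1.0)

    def test_empty_sites_error(self):
        with pytest.raises(ValueError):
            interval_overlap_enrichment([], self._intervals(), 0.1)

    def test_fragmentation_invariance(self):
        sites = [("chr1", p) for p in (5, 50, 95, 300)]
        frac1, _ = interval_overlap_enrichment(sites, self._intervals(), 0.1)
        split = IntervalSet()
        for s, e in ((0, 30), (30, 60), (60, 100)):
            split.add("chr1", s, e, "alu")
        frac2, _ = interval_overlap_enrichment(sites, split, 0.1)
        assert frac1 == frac2


class TestMonomorphic:
    def _matrix(self):
        return GenotypeMatrix(
            pd.DataFrame(
                {
                    "ind1": ["ref/ref", "ref/ref", "ref/ref", np.nan],
                    "ind2": ["ref/ref", "ref/alt", np.nan, np.nan],
                },
                index=["s1", "s2", "s3", "s4"],
            )
        )

    def test_single_het_individual_breaks_monomorphism(self):
        gm = self._matrix()
        assert gm.is_monomorphic_reference("s1")
        assert not gm.is_monomorphic_reference("s2")

    def test_all_missing_site_is_not_monomorphic(self):
        assert not self._matrix().is_monomorphic_reference("s4")

    def test_fraction_and_exclusions(self):
        frac, n_mono, n, n_excl = monomorphic_reference_fraction(
            ["s1", "s2", "s3", "missing"], self._matrix()
        )
        assert (n_mono, n, n_excl) == (2, 3, 1)
        assert frac == pytest.approx(2 / 3)

    def test_unknown_codes_rejected(self):
        with pytest.raises(ValueError):
            GenotypeMatrix(pd.DataFrame({"i": ["0/1"]}, index=["s"]))


class TestRates:
    def test_rate_arithmetic(self):
        rate, per100k = editing_rate(10, 1_000_000)
        assert per100k == pytest.approx(1.0) and rate == pytest.approx(1e-5)

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            editing_rate(1, 0)

    def test_overlapping_placements_count_shared_bases_once(self):
        recs = [
            AlignmentRecord("a", "chr1", 0, 500, 0, 500, "+", 0),
            AlignmentRecord("b", "chr1", 400, 900, 0, 500, "+", 0),
        ]
        assert unique_covered_bp(recs) == 900

    def test_unique_coverage_matches_set_union_oracle(self, rng):
        recs = []
        for i in range(100):
            s = int(rng.integers(0, 5_000))
            ln = int(rng.integers(400, 900))
            recs.append(AlignmentRecord(f"t{i}", "chr1", s, s + ln, 0, ln, "+", 0))
        oracle = set()
        for r in recs:
            oracle.update(range(r.ref_start, r.ref_end))
        assert unique_covered_bp(recs) == len(oracle)

    def test_editing_type_fraction(self):
        tally = {"G>A": 82, "C>T": 72, "A>G": 188, "T>C": 419, "other": 8}
        assert editing_type_fraction(tally) == pytest.approx(100 * 607 / 769)
        assert editing_type_fraction({"G>A": 3, "A>G": 0, "T>C": 0}) == 0.0
        with pytest.raises(ValueError):
            editing_type_fraction({"G>A": 0})
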