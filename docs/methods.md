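# Methods

## Scope and model

`editscan` re-implements, at desk scale, an archive screen for nucleic-acid
editing in raw capillary traces. The underlying biology: ADAR enzymes
deaminate adenosine to inosine in double-stranded RNA, and inosine is read
as G by sequencing, so edited transcripts show clustered A>G mismatches
against the genome (T>C when the read is the opposite strand of the
transcript). APOBEC cytidine deaminases act on the minus strand of
retroelement cDNA during reverse transcription, which surfaces as clustered
G>A mismatches on the plus strand. Both signals are *runs*: maximal blocks
of consecutive same-type mismatches along a read. The principal confounder
is a dye-chemistry basecalling defect in which every peak is preceded by a
small echo of the following peak; in AGA/AGG contexts the echo of the tall A
overwhelms the intrinsically low G peak and the G is called A, producing
G>A runs with AGA→AAA or AGG→AAG centered motifs at low-to-moderate phred.

## Coordinates and conventions

Genomic coordinates are 0-based half-open everywhere (BED convention); trace
coordinates are 0-based in read orientation; the 12-column tabular alignment
dialect is converted from 1-based inclusive on ingestion, with
`sstart > send` encoding minus strand. Mismatch types are reported in read
orientation as 12 unfolded types; complementary pairs (G>A/C>T, A>G/T>C) are
pooled only in statistics. Any non-ACGTN character becomes N at read time,
so the N filters downstream are the single place ambiguity is handled.

## Placement

The internal aligner is seed-and-extend and strictly ungapped: exact
60-mers of the reference are indexed; the oriented query is probed at
half-seed stride; each hit is extended to the maximal window on its diagonal,
stopping at sequence ends or at an N in either sequence (an N cannot be
scored as match or mismatch). Identity is computed over every aligned column
of the extended window. Acceptance: length ≥ 400, identity ≥ 0.97, no
indels, and a unique locus. Two passing candidates are the same locus when
their reference intervals on the same strand overlap reciprocally by ≥ 50%
(seed hits tile a single placement and must not fake multiplicity); two or
more distinct loci discard the trace. The alignment-score cutoff of archive-era
screens is interpreted here as a length threshold of 400 bp. The aligner
exists for synthetic cohorts; archive-scale
alignment, gapped alignment and E-values are out of scope, and externally
computed placements can be ingested instead.

## Run detection and filters

"Consecutive" means consecutive in the ordered mismatch list, not
base-adjacent — runs of five spanning over 100 bp would otherwise be
impossible. `find_runs` partitions the mismatches of a read into maximal
same-type blocks and keeps those of length ≥ `min_run` (5 for the motif
survey, 3 for quality-set construction). The span filter removes runs whose
first and last members lie < 100 bp apart on the trace (short dense clusters
typify locally bad sequence, not editing); under the no-indel rule trace
span equals reference span, so the choice of coordinate system is
unobservable. The motif filter keeps runs whose members share one centered
trace 3-mer; with a single substitution type the reference 3-mer is then
uniform too. A run containing any N-context member (including a mismatch at
a read edge, which has no full 3-mer) is discarded whole — the minimal
faithful filtering unit here is the run, not the trace.

## Quality sets

A trace enters the high-quality ("editing enriched") set when some run of
≥ 3 same-type mismatches of any quality contains ≥ 2 members at phred ≥ 40
with at least one such pair ≥ 100 bp apart; only the predicate-passing
mismatches are reported. The low-quality set mirrors the definition with
phred < 10. The two phred-40 mismatches are required to lie in the *same*
run — the stricter of the two possible readings of the definition, and the
internally consistent one (the run is what types the trace). A trace with
qualifying runs of several types is counted once per type; duplicate
same-type runs count once (the run with most passing members is reported).
Traces without quality scores cannot be assessed and are excluded with a
warning.

## Artifact diagnostics

`motif_artifact_flag` is true for a G>A run in which every member's
(reference, trace) motif pair is AGA→AAA or AGG→AAG. The two contexts mix
freely within one affected read, so the flag accepts mixtures of the two
pairs; on a motif-uniform run it reduces to membership of the run's single
pair. The flag is strand-literal — the artifact is a property of the read
chemistry, not of the genome, so no genomic-strand folding is applied.
`offset_artifact_test` compares a basecaller's primary and second-best call
sequences: the longest block with `alternate[i] == primary[i+d]` is computed
for d = ±1 and the trace is flagged when it reaches `min_block` = 50. The
threshold is a design choice, not an inherited constant: random unrelated
400-mers have an expected longest chance agreement of about log₄(400) ≈ 4–5
bases and flag at well under 1%, while a genuine sub-peak shift agrees over
essentially the whole read.

## Exact statistics

The two-sided Fisher exact test sums the hypergeometric probabilities of
all tables with the observed margins that are no more probable than the
observed table (minimum-likelihood convention; a 1e-7 relative slack absorbs
roundoff at the boundary). It is evaluated in log space via `gammaln`, so
tables with entries near 10⁵ are computed without overflow and agree with
exact integer enumeration to better than 10 significant digits; a zero
margin admits a single table and returns p = 1. Repeat-interval overlap is
scored one-sided binomial against a supplied genome fraction. Upstream
context is measured on the editing-sense strand: for A>G sites the neighbor
is the reference base at site−1; for T>C sites it is the complement of the
base at site+1 — collapsing this orientation demonstrably destroys the
planted upstream-G depletion in simulation, which guards the rule. A SNP
site is monomorphic-reference when every non-missing genotype is
homozygous reference. The editing rate divides editing-type mismatches by
the number of *distinct* reference positions covered by RNA-origin accepted
placements (interval union, shared bases counted once). The DNA-editing
contingency tables treat the genome-wide counts as the background row as
published, without subtracting the focal counts.

## The simulator

The generator emulates the data the scanner was designed for, with defaults
chosen once as the study conditions:

* **Reference** — 100 kb i.i.d. uniform ACGT with 6 planted copies of a
  300 bp repeat at 1% divergence (the retroelement stand-in; copies are
  shorter than the minimum alignment length so they do not defeat unique
  placement, which a dedicated two-copy fixture tests separately).
* **Reads** — 400–900 bp, uniform position and strand; phred-calibrated
  substitution errors (error probability 10^(−q/10) at assigned quality q).
  The quality profile is flat phred 45 with a linear decay to phred 25 over
  the final 20% of the read — a good capillary run; the decay endpoint was
  chosen so that late-read miscalls only rarely interrupt a genuine editing
  cluster, which mirrors the kind of trace the archive screen retained.
* **RNA editing** — half the traces are RNA-origin; half of those carry one
  planted cluster of 5 A>G sites (transcript sense) spanning ≥ 110 bp at
  phred 40–50, placed on reference A's whose 5′ neighbor is non-G with 4:1
  weight (the ADAR signature, sufficient for the context-profile tests).
  Since reads sample both strands, about half of the edited reads surface
  as T>C runs.
* **DNA editing** — repeat-overlapping DNA traces receive G>A clusters
  (phred 35–50) with a 4:1 preference for a downstream G or A (the
  GG-to-AG / GA-to-AA dinucleotide signature of APOBEC3).
* **Artifact** — 20% of traces pass through the sub-peak model: each AGA/AGG
  G is miscalled A with probability 0.55, capped at 2.5% of read length,
  with quality drawn from a right-skewed distribution on [3, 34] (median
  ≈ phred 7, never reaching the phred-40 bar). The probability and cap keep
  affected reads near a 1.7% mismatch rate: the observable artifact
  population consists, by construction, of traces that passed the
  97%-identity screen, and the skew toward low phred reflects that the echo
  peak usually dominates the true peak only marginally (the same model puts
  most artifact mismatches below phred 10, consistent with a low-quality
  set that dwarfs the high-quality one). The alternate-call sequence is the
  primary shifted by +1. The standalone `simulate_subpeak_trace` default
  (miscall 0.9, uniform phred 15–35, no cap) is the denser, undiluted form
  used to characterize the detectors themselves.

Identical configurations (including the seed) produce byte-identical
FASTA/QUAL/truth outputs. What the generator does **not** model: real
chromatogram shapes, indel errors (the pipeline rejects gapped placements by
design), mate pairs, coverage structure, GC bias, or genome-scale repeat
families. Passing the recovery tests therefore shows the pipeline's logic is
correct under phred-calibrated substitution noise, not that archive-scale
counts would be reproduced.

## Problem sizes and numerical choices

The test suite and the acceptance script run on 500-trace cohorts over a
100 kb reference — large enough that recovery rates are stable across seeds
(recall ≥ 0.97, artifact capture 0.93–0.98 in spot checks of eight seeds)
while the whole suite runs in well under a minute apart from the exhaustive
oracle sweeps. The run-detection oracle enumerates all 4-type mismatch
sequences to length 8 directly and lengths 9–12 through canonical label
patterns (restricted growth strings), run structure being label-equivariant
(itself property-tested). The Fisher oracle enumerates every 2×2 table with
total ≤ 30 in exact integer arithmetic. Ties in run detection cannot occur
(maximality is structural); ties in Fisher inclusion are handled by the
1e-7 relative slack noted above. Degenerate inputs (empty mismatch lists,
zero margins, empty site sets, traces shorter than a seed) return empty
results or raise with the offending record named, as documented per
function.

## Known limitations

* The aligner is exact-seed based; a trace whose every probed 60-mer spans a
  mismatch can be missed — negligible at the simulated error rates, but not
  archive-proof.
* The monomorphism machinery assumes a genotype matrix already restricted to
  declared ref/alt sites; it does not parse VCF.
* The published extrapolation that a percentage of catalogued SNPs are
  artifacts, and the archive-scale count tables, are outside what a
  synthetic cohort can reproduce and are not attempted.
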