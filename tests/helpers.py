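"""Small constructors shared across test modules."""

from editscan.cluster_scan import Mismatch


def mk_mismatch(mtype, pos, qual=None, trace_motif="AAA", ref_motif="AGA"):
    ref_base, trace_base = mtype.split(">")
    return Mismatch(
        chrom="chr1", ref_pos=pos, trace_pos=pos, ref_base=ref_base,
        trace_base=trace_base, qual=qual, trace_motif=trace_motif,
        ref_motif=ref_motif,
    )
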