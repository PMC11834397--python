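"""Independent oracles shared by unit and acceptance tests.

These deliberately avoid the code paths they check: the effect oracle
re-derives consequences by editing and translating the whole CDS instead of
codon-local arithmetic.
"""

from halotrace._seq import START_CODONS, revcomp, translate
from halotrace.annotation import Feature, Genome
from halotrace.gd_io import GDMutation


def whole_cds_translation_oracle(m: GDMutation, genome: Genome, f: Feature) -> str:
    """Effect category by applying the edit to the full CDS and translating."""
    seq = genome[f.replicon_id]
    region = seq[f.start - 1 : f.end]
    off = m.position - f.start  # 0-based offset into the + strand region
    if m.record_type == "SNP":
        edited = region[:off] + m.new_seq + region[off + 1 :]
    elif m.record_type == "DEL":
        edited = region[:off] + region[off + m.size :]
    elif m.record_type == "INS":
        edited = region[: off + 1] + m.new_seq + region[off + 1 :]
    else:
        raise AssertionError(f"oracle does not handle {m.record_type}")
    ref_cds = region if f.strand == "+" else revcomp(region)
    alt_cds = edited if f.strand == "+" else revcomp(edited)

    change = len(alt_cds) - len(ref_cds)
    if change % 3 != 0:
        return "frameshift"
    if change != 0:
        return "in_frame_indel"
    if alt_cds[:3] != ref_cds[:3]:
        # Initiation survives iff the new first codon is still a valid start.
        return "synonymous" if alt_cds[:3] in START_CODONS else "start_loss"
    ref_prot, alt_prot = translate(ref_cds), translate(alt_cds)
    if ref_prot == alt_prot:
        return "synonymous"
    diffs = [i for i, (a, b) in enumerate(zip(ref_prot, alt_prot)) if a != b]
    if any(alt_prot[i] == "*" for i in diffs):
        return "nonsense"
    return "nonsynonymous"
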