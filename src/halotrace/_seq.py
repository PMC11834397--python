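"""Small shared sequence primitives: complements, translation, indel alignment."""

from __future__ import annotations

from Bio.Seq import Seq

#: Standard genetic code is used; archaeal CDSs are translated with table 11
#: so that alternative initiation contexts (GTG/TTG) are recognized.
TRANSLATION_TABLE = 11

START_CODONS = frozenset({"ATG", "GTG", "TTG"})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    return str(Seq(seq).translate(table=TRANSLATION_TABLE))


def codon_to_aa(codon: str) -> str:
    return translate(codon)


def run_bounds(seq: str, pos: int) -> tuple[int, int]:
    """1-based inclusive bounds of the mononucleotide run containing ``pos``."""
    base = seq[pos - 1]
    lo = pos
    while lo > 1 and seq[lo - 2] == base:
        lo -= 1
    hi = pos
    while hi < len(seq) and seq[hi] == base:
        hi += 1
    return lo, hi


def left_align_deletion(ref: str, position: int, size: int) -> int:
    """Left-align a deletion of ``size`` bases starting at 1-based ``position``.

    The deletion is shifted left while the base immediately before it equals
    the last deleted base (the resulting reference sequence is unchanged by
    the shift).  Returns the normalized 1-based start position.
    """
    pos = position
    while pos > 1 and ref[pos - 2] == ref[pos + size - 2]:
        pos -= 1
    return pos


def left_align_insertion(ref: str, position: int, inserted: str) -> tuple[int, str]:
    """Left-align an insertion of ``inserted`` after 1-based ``position``.

    The insertion is rotated leftwards while the last inserted base equals
    the reference base it is inserted after.  Returns the normalized
    (position, inserted sequence) pair.
    """
    pos, seq = position, inserted
    while pos >= 1 and pos <= len(ref) and seq[-1] == ref[pos - 1]:
        seq = ref[pos - 1] + seq[:-1]
        pos -= 1
    return pos, seq
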