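"""Effect annotation: codon arithmetic, mobilome, repeats, homopolymers."""

import numpy as np
import pytest
from intervaltree import IntervalTree

from halotrace._seq import revcomp
from halotrace.annotation import (
    CoordinateError,
    Feature,
    FeatureIndex,
    Genome,
    classify_effect,
    contained_in_repeat,
    homopolymer_context,
    is_mobilome,
    overlaps_repeat,
)
from halotrace.gd_io import GDMutation


def _snp(replicon, pos, new):
    return GDMutation("SNP", "1", [], replicon, pos, [new])


def _codon_pos(f: Feature, codon_idx: int, within: int) -> int:
    if f.strand == "+":
        return f.start + codon_idx * 3 + within
    return f.end - (codon_idx * 3 + within)


def _coding_base(base, strand):
    return base if strand == "+" else {"A": "T", "T": "A", "C": "G", "G": "C"}[base]


# --- codon-level SNP effects ----------------------------------------------


@pytest.mark.parametrize("gene_key", ["geneA", "geneB"])
def test_leucine_to_proline_snp_is_nonsynonymous(toy_genome, gene_key):
    """CTG -> CCG at a planted codon changes Leu to Pro on either strand."""
    f = toy_genome[gene_key]
    pos = _codon_pos(f, 5, 1)
    eff = classify_effect(
        _snp(f.replicon_id, pos, _coding_base("C", f.strand)),
        toy_genome["genome"],
        toy_genome["features"],
    )
    assert eff.category == "nonsynonymous"
    assert eff.amino_acid_change == ("L", 6, "P")


@pytest.mark.parametrize("gene_key", ["geneA", "geneB"])
def test_start_codon_atg_to_ata_is_start_loss(toy_genome, gene_key):
    f = toy_genome[gene_key]
    pos = _codon_pos(f, 0, 2)
    eff = classify_effect(
        _snp(f.replicon_id, pos, _coding_base("A", f.strand)),
        toy_genome["genome"],
        toy_genome["features"],
    )
    assert eff.category == "start_loss"


def test_ggc_to_ggt_is_synonymous(toy_genome):
    f = toy_genome["geneA"]
    eff = classify_effect(
        _snp(f.replicon_id, _codon_pos(f, 10, 2), "T"),
        toy_genome["genome"],
        toy_genome["features"],
    )
    assert eff.category == "synonymous"


def test_tryptophan_to_stop_is_nonsense(toy_genome):
    f = toy_genome["geneA"]  # codon 20 planted TGG
    eff = classify_effect(
        _snp(f.replicon_id, _codon_pos(f, 20, 2), "A"),
        toy_genome["genome"],
        toy_genome["features"],
    )
    assert eff.category == "nonsense"


def test_snp_outside_features_is_intergenic_with_flanks(toy_genome):
    f = toy_genome["geneA"]
    eff = classify_effect(
        _snp("chromosome", f.end + 10, "A"),
        toy_genome["genome"],
        toy_genome["features"],
    )
    assert eff.category == "intergenic"
    up, down = eff.distances_to_flanks
    assert up == 10 and down is not None


def test_coordinates_outside_replicon_raise(toy_genome):
    with pytest.raises(CoordinateError):
        classify_effect(
            _snp("chromosome", 10_000_000, "A"),
            toy_genome["genome"],
            toy_genome["features"],
        )


def test_deletion_categories(toy_genome):
    g, idx = toy_genome["genome"], toy_genome["features"]
    f = toy_genome["geneA"]
    full = GDMutation("DEL", "1", [], f.replicon_id, f.start - 5, [str(f.length + 10)])
    assert classify_effect(full, g, idx).category == "gene_deletion"
    in_frame = GDMutation("DEL", "1", [], f.replicon_id, f.start + 9, ["9"])
    assert classify_effect(in_frame, g, idx).category == "in_frame_indel"
    shift = GDMutation("DEL", "1", [], f.replicon_id, f.start + 9, ["7"])
    assert classify_effect(shift, g, idx).category == "frameshift"
    plasmid_len = len(g["plasmid"])
    loss = GDMutation("DEL", "1", [], "plasmid", 1, [str(plasmid_len)])
    assert classify_effect(loss, g, idx).category == "replicon_loss"


def test_pseudogene_mutation_reported_as_pseudogene(toy_genome):
    f = toy_genome["pseudo"]
    eff = classify_effect(
        _snp(f.replicon_id, f.start + 10, "A"),
        toy_genome["genome"],
        toy_genome["features"],
    )
    assert eff.category == "pseudogene"
    assert eff.amino_acid_change is None


# --- whole-CDS translation oracle -----------------------------------------

from helpers_oracles import whole_cds_translation_oracle


def test_effect_caller_matches_whole_cds_translation_oracle(toy_genome):
    """1,000 random in-CDS edits: codon arithmetic equals full-translation oracle."""
    rng = np.random.default_rng(11)
    genome, idx = toy_genome["genome"], toy_genome["features"]
    genes = [toy_genome[k] for k in ("geneA", "geneB", "geneP")]
    agree = 0
    for _ in range(1000):
        f = genes[rng.integers(0, len(genes))]
        kind = rng.integers(0, 3)
        if kind == 0:
            pos = int(rng.integers(f.start, f.end + 1))
            ref = genome[f.replicon_id][pos - 1]
            new = "ACGT"[rng.integers(0, 4)]
            while new == ref:
                new = "ACGT"[rng.integers(0, 4)]
            m = _snp(f.replicon_id, pos, new)
        elif kind == 1:
            size = int(rng.integers(1, 12))
            pos = int(rng.integers(f.start + 3, f.end - size - 2))
            m = GDMutation("DEL", "1", [], f.replicon_id, pos, [str(size)])
        else:
            ins = "".join(np.array(list("ACGT"))[rng.integers(0, 4, rng.integers(1, 10))])
            pos = int(rng.integers(f.start + 3, f.end - 3))
            m = GDMutation("INS", "1", [], f.replicon_id, pos, [ins])
        got = classify_effect(m, genome, idx).category
        want = whole_cds_translation_oracle(m, genome, f)
        assert got == want, (m, got, want)
        agree += 1
    assert agree == 1000


def test_strand_symmetry_of_effect_categories(toy_genome):
    """Reverse-complementing the genome and flipping strands preserves categories."""
    genome, idx = toy_genome["genome"], toy_genome["features"]
    flipped_genome = Genome({rid: revcomp(s) for rid, s in genome.replicons.items()})
    lengths = genome.lengths

    def flip_feature(f: Feature) -> Feature:
        L = lengths[f.replicon_id]
        return Feature(
            replicon_id=f.replicon_id,
            start=L - f.end + 1,
            end=L - f.start + 1,
            strand="-" if f.strand == "+" else "+",
            kind=f.kind,
            locus_tag=f.locus_tag,
            product=f.product,
        )

    flipped_idx = FeatureIndex([flip_feature(f) for f in idx.features])
    rng = np.random.default_rng(5)
    genes = [toy_genome[k] for k in ("geneA", "geneB")]
    for _ in range(200):
        f = genes[rng.integers(0, 2)]
        pos = int(rng.integers(f.start, f.end + 1))
        ref = genome[f.replicon_id][pos - 1]
        new = "ACGT"[rng.integers(0, 4)]
        while new == ref:
            new = "ACGT"[rng.integers(0, 4)]
        m = _snp(f.replicon_id, pos, new)
        L = lengths[f.replicon_id]
        mirrored = _snp(f.replicon_id, L - pos + 1, revcomp(new))
        a = classify_effect(m, genome, idx).category
        b = classify_effect(mirrored, flipped_genome, flipped_idx).category
        assert a == b


# --- mobilome --------------------------------------------------------------


def test_mobilome_membership(toy_genome):
    idx = toy_genome["features"]
    isg = toy_genome["is_gene"]
    del_is = GDMutation("DEL", "1", [], isg.replicon_id, isg.start - 2, [str(isg.length + 4)])
    assert is_mobilome(del_is, idx) is True
    f = toy_genome["geneA"]  # "widget synthase"
    assert is_mobilome(_snp(f.replicon_id, f.start + 5, "A"), idx) is False
    assert is_mobilome(_snp(isg.replicon_id, isg.start + 5, "A"), idx) is True
    mob = GDMutation("MOB", "1", [], "chromosome", 5, ["ISH8", "1", "0"])
    assert is_mobilome(mob, idx) is True  # MOB records are mobilome by definition


def test_mobilome_is_monotone_in_pattern_set(toy_genome):
    idx = toy_genome["features"]
    rng = np.random.default_rng(3)
    base = (r"transposase",)
    extended = base + (r"widget", r"ISH")
    for _ in range(100):
        pos = int(rng.integers(1, len(toy_genome["genome"]["chromosome"])))
        m = _snp("chromosome", pos, "A")
        if is_mobilome(m, idx, base):
            assert is_mobilome(m, idx, extended)


# --- homopolymer context ----------------------------------------------------


def test_homopolymer_tract_deletion_flagged(toy_genome):
    g = toy_genome["genome"]
    pos = toy_genome["tract_start"] + 3  # inside the 7-C run
    m = GDMutation("DEL", "1", [], "chromosome", pos, ["1"])
    assert homopolymer_context(m, g, min_run=6) is True
    assert homopolymer_context(m, g, min_run=8) is False


def test_isolated_base_deletion_not_flagged(toy_genome):
    g = toy_genome["genome"]
    seq = g["chromosome"]
    # Find a base whose neighbours differ from it (run of one).
    pos = next(
        i + 1
        for i in range(1, len(seq) - 1)
        if seq[i] != seq[i - 1] and seq[i] != seq[i + 1]
    )
    m = GDMutation("DEL", "1", [], "chromosome", pos, ["1"])
    assert homopolymer_context(m, g, min_run=6) is False


def test_homopolymer_requires_single_base_indel(toy_genome):
    m = GDMutation("DEL", "1", [], "chromosome", 10, ["3"])
    with pytest.raises(ValueError):
        homopolymer_context(m, toy_genome["genome"])


def test_homopolymer_scan_matches_run_length_oracle():
    """Exhaustive 1-bp deletions over a synthetic sequence vs a naive scanner."""
    rng = np.random.default_rng(9)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 800)])
    seq = seq[:200] + "G" * 7 + seq[200:500] + "C" * 6 + seq[500:]
    genome = Genome({"chr": seq})

    def naive_run_length(s, p):  # longest run containing 1-based p after left shift
        # Left-align the single-base deletion: deleting any base of a run is
        # equivalent to deleting its first base.
        base = s[p - 1]
        lo = p
        while lo > 1 and s[lo - 2] == base:
            lo -= 1
        hi = p
        while hi < len(s) and s[hi] == base:
            hi += 1
        return hi - lo + 1

    for pos in range(2, len(seq)):
        m = GDMutation("DEL", "1", [], "chr", pos, ["1"])
        assert homopolymer_context(m, genome, min_run=6) == (
            naive_run_length(seq, pos) >= 6
        ), pos


# --- repeats ----------------------------------------------------------------


def _tree(intervals):
    t = IntervalTree()
    for s, e in intervals:
        t[s : e + 1] = True
    return {"chr": t}


def test_repeat_overlap_basics():
    m = _snp("chr", 100, "A")
    assert overlaps_repeat(m, _tree([(50, 150)])) is True
    assert overlaps_repeat(m, {}) is False
    assert overlaps_repeat(m, _tree([(150, 250)])) is False


def test_repeat_overlap_matches_brute_force():
    rng = np.random.default_rng(21)
    intervals = [
        (int(s), int(s + rng.integers(1, 200)))
        for s in rng.integers(1, 5000, size=30)
    ]
    repeats = _tree(intervals)
    for _ in range(300):
        start = int(rng.integers(1, 5200))
        size = int(rng.integers(1, 50))
        m = GDMutation("DEL", "1", [], "chr", start, [str(size)])
        brute = any(start <= e and start + size - 1 >= s for s, e in intervals)
        assert overlaps_repeat(m, repeats) == brute


def test_containment_spares_large_deletions():
    repeats = _tree([(100, 200)])
    inside = GDMutation("DEL", "1", [], "chr", 120, ["10"])
    spanning = GDMutation("DEL", "1", [], "chr", 50, ["500"])
    assert contained_in_repeat(inside, repeats) is True
    assert contained_in_repeat(spanning, repeats) is False
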