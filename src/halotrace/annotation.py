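"""Functional context of mutations: coding effect, mobilome, repeats, homopolymers.

This module loads the reference genome (FASTA) and its feature annotation
(GFF3), and determines for each mutation record its consequence category
(synonymous / nonsynonymous / start-loss / frameshift / ...), the loci it
touches, whether it falls in the mobilome (IS elements and transposase
genes), whether it overlaps a user-supplied repeat region, and whether a
single-base indel sits in a homopolymer tract (a sequencing-error-prone
context).

Coordinates are 1-based inclusive, matching GFF3 and GenomeDiff; BED input
is converted from 0-based half-open on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from intervaltree import IntervalTree

from ._seq import (
    START_CODONS,
    codon_to_aa,
    left_align_deletion,
    revcomp,
    run_bounds,
)
from .gd_io import GDMutation

#: Case-insensitive patterns defining the mobilome: a feature belongs to the
#: mobilome if its product/kind text matches any of these.  Covers IS-family
#: transposases ("IS5 family transposase", "IS4-like element ISH8B",
#: "ISH3-like element ISH27-2") and generic transposase annotations.
DEFAULT_MOBILOME_PATTERNS = (
    r"transposase",
    r"insertion sequence",
    r"\bIS\d",
    r"ISH",
)

#: Minimum mononucleotide run length for a single-base indel to be flagged as
#: a homopolymer-tract artifact candidate.
DEFAULT_HOMOPOLYMER_MIN_RUN = 6

#: Fraction of a replicon a deletion must span to count as loss of the
#: whole replicon.
DEFAULT_REPLICON_LOSS_FRACTION = 0.99

#: Consequence categories, most severe first; a mutation overlapping several
#: features takes the most severe applicable category.
SEVERITY_ORDER = (
    "replicon_loss",
    "gene_deletion",
    "frameshift",
    "nonsense",
    "start_loss",
    "nonsynonymous",
    "in_frame_indel",
    "synonymous",
    "pseudogene",
    "intergenic",
)

_SEVERITY_RANK = {cat: i for i, cat in enumerate(SEVERITY_ORDER)}


class CoordinateError(ValueError):
    """Mutation coordinates fall outside the named replicon."""


@dataclass
class Genome:
    """Reference sequences, one uppercase string per replicon."""

    replicons: dict[str, str]

    def __post_init__(self) -> None:
        if any(not s for s in self.replicons.values()):
            raise ValueError("replicon sequences must be non-empty")
        self.replicons = {k: v.upper() for k, v in self.replicons.items()}

    def __contains__(self, replicon: str) -> bool:
        return replicon in self.replicons

    def __getitem__(self, replicon: str) -> str:
        return self.replicons[replicon]

    @property
    def lengths(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.replicons.items()}

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(seqs)


@dataclass(frozen=True)
class Feature:
    """A genome feature with 1-based inclusive coordinates."""

    replicon_id: str
    start: int
    end: int
    strand: str
    kind: str  # CDS, pseudogene, other
    locus_tag: str
    product: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad feature interval {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class FeatureIndex:
    """Interval-queryable collection of features, one tree per replicon."""

    def __init__(self, features: list[Feature]):
        self.features = list(features)
        self._trees: dict[str, IntervalTree] = {}
        for f in self.features:
            tree = self._trees.setdefault(f.replicon_id, IntervalTree())
            tree[f.start : f.end + 1] = f

    def overlapping(self, replicon: str, start: int, end: int) -> list[Feature]:
        """Features intersecting the 1-based inclusive interval [start, end]."""
        tree = self._trees.get(replicon)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end + 1)]
        return sorted(hits, key=lambda f: (f.start, f.end, f.locus_tag))

    def on_replicon(self, replicon: str) -> list[Feature]:
        return sorted(
            (f for f in self.features if f.replicon_id == replicon),
            key=lambda f: (f.start, f.end),
        )


def load_gff3(path) -> FeatureIndex:
    """Load CDS and pseudogene features from a GFF3 file.

    Pseudogenes are recognized from the ``pseudogene`` feature type or a
    ``pseudo=true`` attribute on a gene/CDS; all other feature types are
    ignored (regulatory and RNA genes are out of scope here).
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    features: list[Feature] = []
    for ftype in ("CDS", "pseudogene"):
        for rec in db.features_of_type(ftype):
            pseudo = ftype == "pseudogene" or rec.attributes.get("pseudo", ["false"])[
                0
            ].lower() in ("true", "1")
            features.append(
                Feature(
                    replicon_id=rec.seqid,
                    start=rec.start,
                    end=rec.end,
                    strand=rec.strand if rec.strand in "+-" else "+",
                    kind="pseudogene" if pseudo else "CDS",
                    locus_tag=rec.attributes.get("locus_tag", [rec.id or "?"])[0],
                    product=rec.attributes.get("product", [""])[0],
                )
            )
    return FeatureIndex(features)


def load_repeats_bed(path) -> dict[str, IntervalTree]:
    """Load repeat intervals from BED (0-based half-open → 1-based inclusive)."""
    trees: dict[str, IntervalTree] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        replicon, start0, end0 = cols[0], int(cols[1]), int(cols[2])
        trees.setdefault(replicon, IntervalTree())[start0 + 1 : end0 + 1] = True
    return trees


@dataclass
class EffectAnnotation:
    """Functional consequence of one mutation."""

    category: str
    affected_locus_tags: list[str] = field(default_factory=list)
    amino_acid_change: tuple[str, int, str] | None = None
    distances_to_flanks: tuple[int | None, int | None] | None = None
    mobilome: bool = False
    repeat_overlap: bool = False
    homopolymer_artifact_candidate: bool = False

    def __post_init__(self) -> None:
        aa_categories = {"nonsynonymous", "synonymous", "start_loss", "nonsense"}
        has_aa = self.amino_acid_change is not None
        if has_aa != (self.category in aa_categories):
            raise ValueError(
                f"amino_acid_change must be present iff category is codon-level "
                f"(category={self.category}, change={self.amino_acid_change})"
            )

    @property
    def coding(self) -> bool:
        """Whether the consequence alters a protein product."""
        return self.category in {
            "nonsynonymous",
            "start_loss",
            "nonsense",
            "frameshift",
            "in_frame_indel",
            "gene_deletion",
            "replicon_loss",
        }


def _footprint(m: GDMutation) -> tuple[int, int]:
    return m.position, m.end


def _net_length_change(m: GDMutation) -> int:
    if m.record_type == "INS":
        return len(m.new_seq)
    if m.record_type == "DEL":
        return -m.size
    if m.record_type == "SUB":
        return len(m.new_seq) - m.size
    if m.record_type == "AMP":
        return m.size * (int(m.payload[1]) - 1)
    return 0


def _snp_effect(m: GDMutation, seq: str, cds: Feature):
    """Codon arithmetic for a SNP inside a CDS; returns (category, aa_change)."""
    if cds.strand == "+":
        offset = m.position - cds.start
        new_base = m.new_seq
    else:
        offset = cds.end - m.position
        new_base = revcomp(m.new_seq)
    codon_idx = offset // 3
    within = offset % 3
    if cds.strand == "+":
        codon_start = cds.start + codon_idx * 3
        ref_codon = seq[codon_start - 1 : codon_start + 2]
    else:
        coding = revcomp(seq[cds.start - 1 : cds.end])
        ref_codon = coding[codon_idx * 3 : codon_idx * 3 + 3]
    alt_codon = ref_codon[:within] + new_base + ref_codon[within + 1 :]

    if codon_idx == 0:
        # The annotated start codon: what matters is whether initiation
        # survives, not the codon's in-frame amino acid.  A change to any
        # valid start codon (ATG/GTG/TTG) is treated as silent.
        if alt_codon in START_CODONS:
            return "synonymous", ("M", 1, "M")
        return "start_loss", ("M", 1, codon_to_aa(alt_codon))
    ref_aa = codon_to_aa(ref_codon)
    alt_aa = codon_to_aa(alt_codon)
    change = (ref_aa, codon_idx + 1, alt_aa)
    if alt_aa == ref_aa:
        return "synonymous", change
    if alt_aa == "*":
        return "nonsense", change
    return "nonsynonymous", change


def classify_effect(
    m: GDMutation,
    genome: Genome,
    features: FeatureIndex,
    replicon_loss_fraction: float = DEFAULT_REPLICON_LOSS_FRACTION,
) -> EffectAnnotation:
    """Determine the consequence category of one mutation.

    SNPs inside a CDS are resolved by codon arithmetic on the coding strand
    (reverse-strand CDSs via reverse complement); indels by length modulo 3;
    deletions spanning a whole CDS are gene deletions and deletions spanning
    (almost) a whole replicon are replicon losses.  Anything outside CDS and
    pseudogene features is intergenic, with distances to the nearest flanking
    genes.  A mutation overlapping several features takes the most severe
    applicable category and reports every touched locus.
    """
    if m.replicon not in genome:
        raise CoordinateError(f"unknown replicon {m.replicon!r}")
    seq = genome[m.replicon]
    start, end = _footprint(m)
    if not (1 <= start <= end <= len(seq)):
        raise CoordinateError(
            f"{m.record_type} {start}..{end} outside {m.replicon} (len {len(seq)})"
        )

    if m.record_type == "DEL" and m.size >= replicon_loss_fraction * len(seq):
        loci = [f.locus_tag for f in features.on_replicon(m.replicon)]
        return EffectAnnotation(category="replicon_loss", affected_locus_tags=loci)

    hits = features.overlapping(m.replicon, start, end)
    loci = [f.locus_tag for f in hits]

    if not hits:
        up, down = _flank_distances(features, m.replicon, start, end)
        return EffectAnnotation(
            category="intergenic",
            distances_to_flanks=(up, down),
        )

    best_category = "intergenic"
    best_change = None
    for f in hits:
        if f.kind == "pseudogene":
            category, change = "pseudogene", None
        elif m.record_type == "SNP":
            category, change = _snp_effect(m, seq, f)
        elif m.record_type == "DEL" and start <= f.start and end >= f.end:
            category, change = "gene_deletion", None
        else:
            net = _net_length_change(m)
            category = "in_frame_indel" if net % 3 == 0 else "frameshift"
            change = None
            if m.record_type == "MOB":
                # A mobile-element insertion into a CDS disrupts it.
                category = "frameshift"
        if _SEVERITY_RANK[category] < _SEVERITY_RANK[best_category]:
            best_category, best_change = category, change

    return EffectAnnotation(
        category=best_category,
        affected_locus_tags=loci,
        amino_acid_change=best_change,
    )


def _flank_distances(
    features: FeatureIndex, replicon: str, start: int, end: int
) -> tuple[int | None, int | None]:
    """Distances (bp) from an intergenic footprint to the nearest genes."""
    up = down = None
    for f in features.on_replicon(replicon):
        if f.end < start:
            d = start - f.end
            up = d if up is None or d < up else up
        elif f.start > end:
            d = f.start - end
            down = d if down is None or d < down else down
    return up, down


def is_mobilome(
    m: GDMutation,
    features: FeatureIndex,
    patterns=DEFAULT_MOBILOME_PATTERNS,
) -> bool:
    """Whether the mutation's footprint lies in the mobilome.

    True iff the footprint intersects a feature whose product or kind matches
    any mobilome pattern (case-insensitive).  MOB-type records — mobile
    element insertions — are mobilome by definition.
    """
    if m.record_type == "MOB":
        return True
    start, end = _footprint(m)
    compiled = [re.compile(p, re.IGNORECASE) for p in patterns]
    for f in features.overlapping(m.replicon, start, end):
        text = f"{f.product} {f.kind}"
        if any(p.search(text) for p in compiled):
            return True
    return False


def homopolymer_context(
    m: GDMutation, genome: Genome, min_run: int = DEFAULT_HOMOPOLYMER_MIN_RUN
) -> bool:
    """Whether a single-base indel sits in a mononucleotide run of >= min_run.

    Single-base indels inside homopolymer tracts are the classic short-read
    sequencing artifact and are flagged as artifact candidates (they are not
    filtered out; the flag travels with the annotation).
    """
    single_ins = m.record_type == "INS" and len(m.new_seq) == 1
    single_del = m.record_type == "DEL" and m.size == 1
    if not (single_ins or single_del):
        raise ValueError("homopolymer_context requires a single-base INS or DEL")
    seq = genome[m.replicon]
    if single_del:
        pos = left_align_deletion(seq, m.position, 1)
        base = seq[pos - 1]
    else:
        base = m.new_seq
        # The insertion extends a run only if it matches an adjacent base.
        if m.position <= len(seq) and seq[m.position - 1] == base:
            pos = m.position
        elif m.position < len(seq) and seq[m.position] == base:
            pos = m.position + 1
        else:
            return False
    lo, hi = run_bounds(seq, pos)
    if seq[pos - 1] != base:
        return False
    return hi - lo + 1 >= min_run


def overlaps_repeat(m: GDMutation, repeats: dict[str, IntervalTree]) -> bool:
    """Whether the mutation's footprint intersects any repeat interval."""
    tree = repeats.get(m.replicon)
    if tree is None:
        return False
    start, end = _footprint(m)
    return bool(tree.overlap(start, end + 1))


def contained_in_repeat(m: GDMutation, repeats: dict[str, IntervalTree]) -> bool:
    """Whether the mutation's footprint lies entirely inside one repeat interval.

    This is the criterion used for *filtering*: a point mutation or small
    indel called inside repetitive sequence is unreliable with short reads,
    but a large deletion that merely spans a repeat (up to and including a
    whole-replicon loss) is not itself a repeat artifact and is kept.
    ``overlaps_repeat`` (any intersection) remains the annotation flag.
    """
    tree = repeats.get(m.replicon)
    if tree is None:
        return False
    start, end = _footprint(m)
    return any(iv.begin <= start and iv.end > end for iv in tree.overlap(start, end + 1))


def annotate(
    m: GDMutation,
    genome: Genome,
    features: FeatureIndex,
    repeats: dict[str, IntervalTree] | None = None,
    mobilome_patterns=DEFAULT_MOBILOME_PATTERNS,
    homopolymer_min_run: int = DEFAULT_HOMOPOLYMER_MIN_RUN,
    replicon_loss_fraction: float = DEFAULT_REPLICON_LOSS_FRACTION,
) -> EffectAnnotation:
    """Full annotation of one mutation (effect + mobilome + repeat + homopolymer)."""
    eff = classify_effect(m, genome, features, replicon_loss_fraction)
    eff.mobilome = is_mobilome(m, features, mobilome_patterns)
    eff.repeat_overlap = overlaps_repeat(m, repeats or {})
    single_indel = (m.record_type == "INS" and len(m.new_seq) == 1) or (
        m.record_type == "DEL" and m.size == 1
    )
    if single_indel:
        eff.homopolymer_artifact_candidate = homopolymer_context(
            m, genome, homopolymer_min_run
        )
    return eff
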