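"""Curated two-species laboratory strain panels (synthetic coordinates).

This module reconstructs, as runnable input data, the published strain
panels of the two model haloarchaea — *Halobacterium salinarum* NRC-1
(22 sequenced strains: a lab wild type, two samplings of the Δura3 parental
stock and 19 knockouts across two labs) and *Haloferax volcanii* DS2
(39 sequenced strains: a lab wild type, four sequenced parentals and 34
knockouts across seven labs) — together with the curated per-mutation
catalog of each panel: which strains carry each mutation, and what kind of
event it is (nonsynonymous / synonymous / start-loss SNPs, small indels,
homopolymer-tract indels, IS-element deletions, a whole-replicon loss,
intended marker deletions, ...).

SYNTHETIC STAND-IN NOTE: the real multi-megabase reference genomes cannot
ship here, so every mutation is re-embedded at a synthetic coordinate on a
small generated replicon whose named genes carry the documented products
and designed codons.  The strain-by-mutation presence patterns, lineage
topology, event types and intended-edit structure are the curated content;
genomic coordinates and surrounding sequence are synthetic.  Nothing
downstream reads the curated class labels: classes, effects and summary
statistics are recomputed from the emitted GenomeDiff documents by the
ordinary pipeline, which is what makes these panels useful as end-to-end
fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .annotation import Feature, FeatureIndex, Genome
from .catalog import IntendedEdit, StrainInfo, StrainManifest
from .gd_io import GDDocument, GDEvidence, GDMutation
from .lineage import LineageGraph
from .synthetic_data import RepliconBuilder

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class StudyMutation:
    """One curated mutation: a concrete GD record plus its carrier strains."""

    name: str
    template: GDMutation
    carriers: frozenset[str]
    note: str = ""


@dataclass
class StudyScenario:
    """A complete species panel ready to run through the pipeline."""

    species: str
    genome: Genome
    features: FeatureIndex
    manifest: StrainManifest
    graph: LineageGraph
    mutations: list[StudyMutation]
    #: Strains excluded from per-strain statistics (not from classification):
    #: knockouts whose calls are dominated by parent-construction artifacts.
    exclude_strains: frozenset[str] = frozenset()
    noise_strains: tuple[str, ...] = ()

    def docs(self) -> dict[str, GDDocument]:
        """Per-strain GenomeDiff documents (carried mutations + light noise)."""
        docs: dict[str, GDDocument] = {}
        for strain in sorted(self.graph.sequenced):
            counter = 1
            records = []
            for sm in self.mutations:
                if strain not in sm.carriers:
                    continue
                t = sm.template
                records.append(
                    GDMutation(
                        record_type=t.record_type,
                        id=str(counter),
                        parent_evidence_ids=[],
                        replicon=t.replicon,
                        position=t.position,
                        payload=list(t.payload),
                        attributes=dict(t.attributes),
                    )
                )
                counter += 1
            evidence = []
            if strain in self.noise_strains:
                # One marginal call and one unassigned-coverage evidence
                # record, exercising the exclusion rules on real input.
                records.append(
                    GDMutation(
                        record_type="SNP",
                        id=str(counter),
                        parent_evidence_ids=[],
                        replicon=self._chrom,
                        position=40 + counter,
                        payload=["A" if self.genome[self._chrom][39 + counter] != "A" else "C"],
                        attributes={"reject": "FREQUENCY_CUTOFF"},
                    )
                )
                counter += 1
                evidence.append(
                    GDEvidence(
                        record_type="UN",
                        id=str(counter),
                        parent_evidence_ids=[],
                        fields=[self._chrom, "5", "25"],
                    )
                )
                counter += 1
            docs[strain] = GDDocument(
                metadata=[("GENOME_DIFF", "1.0"), ("TITLE", strain)],
                mutations=records,
                evidence=evidence,
                strain_id=strain,
            )
        return docs

    @property
    def _chrom(self) -> str:
        return "chromosome"


# ---------------------------------------------------------------------------
# Small design helpers: SNPs at planted codons, so any seed works.


def _snp(f: Feature, codon_idx: int, within: int, new_coding_base: str) -> tuple[str, int, str]:
    """(replicon, genomic position, genomic new base) for a coding-frame SNP."""
    if f.strand == "+":
        pos = f.start + codon_idx * 3 + within
        new = new_coding_base
    else:
        pos = f.end - (codon_idx * 3 + within)
        new = _COMP[new_coding_base]
    return f.replicon_id, pos, new


def _mut(rtype: str, replicon: str, pos: int, payload: list[str], attrs=None) -> GDMutation:
    return GDMutation(
        record_type=rtype,
        id="t",
        parent_evidence_ids=[],
        replicon=replicon,
        position=pos,
        payload=payload,
        attributes=dict(attrs or {}),
    )


class _PanelBuilder:
    """Accumulates replicons, genes and curated mutations for one species."""

    def __init__(self, species: str, seed: int):
        self.species = species
        self.rng = np.random.default_rng(seed)
        self.builders: dict[str, RepliconBuilder] = {}
        self.loci: dict[str, Feature] = {}
        self.pending: list[tuple] = []  # deferred records needing final sequence
        self.mutations: list[StudyMutation] = []
        self._spacer_marks: dict[str, tuple[str, int]] = {}

    def replicon(self, rid: str) -> RepliconBuilder:
        b = RepliconBuilder(rid, self.rng)
        b.add_spacer(100)
        self.builders[rid] = b
        return b

    def gene(
        self,
        b: RepliconBuilder,
        locus: str,
        product: str = "hypothetical protein",
        n: int = 150,
        strand: str = "+",
        kind: str = "CDS",
        overrides: dict[int, str] | None = None,
        spacer: int = 150,
    ) -> Feature:
        f = b.add_cds(locus, product, n, strand, kind=kind, codon_overrides=overrides)
        self.loci[locus] = f
        self._spacer_marks[locus] = (b.replicon_id, b.pos)  # spacer start after gene
        b.add_spacer(spacer)
        return f

    # --- curated mutation constructors -------------------------------------

    def add(self, name: str, template: GDMutation, carriers, note: str = "") -> None:
        self.mutations.append(
            StudyMutation(name=name, template=template, carriers=frozenset(carriers), note=note)
        )

    def snp_nonsyn(self, locus, carriers, idx=10, name=None, note=""):
        f = self.loci[locus]
        rep, pos, new = _snp(f, idx, 0, "C")  # planted GCT -> CCT (Ala->Pro)
        self.add(name or f"snp_{locus}_{idx}", _mut("SNP", rep, pos, [new]), carriers, note)

    def snp_syn(self, locus, carriers, idx=10, name=None, note=""):
        f = self.loci[locus]
        rep, pos, new = _snp(f, idx, 2, "T")  # planted GGC -> GGT (Gly silent)
        self.add(name or f"syn_{locus}_{idx}", _mut("SNP", rep, pos, [new]), carriers, note)

    def snp_s2r(self, locus, carriers, idx=10, name=None, note=""):
        f = self.loci[locus]
        rep, pos, new = _snp(f, idx, 2, "A")  # planted AGC -> AGA (Ser->Arg)
        self.add(name or f"snp_{locus}_{idx}", _mut("SNP", rep, pos, [new]), carriers, note)

    def snp_l2p(self, locus, carriers, idx=10, name=None, note=""):
        f = self.loci[locus]
        rep, pos, new = _snp(f, idx, 1, "C")  # planted CTG -> CCG (Leu->Pro)
        self.add(name or f"snp_{locus}_{idx}", _mut("SNP", rep, pos, [new]), carriers, note)

    def snp_start_loss(self, locus, carriers, name=None, note=""):
        f = self.loci[locus]
        rep, pos, new = _snp(f, 0, 2, "A")  # ATG -> ATA
        self.add(name or f"startloss_{locus}", _mut("SNP", rep, pos, [new]), carriers, note)

    def del_in_gene(self, locus, carriers, size, offset=31, name=None, note=""):
        """Deletion of ``size`` bp starting ``offset`` bp into the gene."""
        f = self.loci[locus]
        self.add(
            name or f"del{size}_{locus}",
            _mut("DEL", f.replicon_id, f.start + offset, [str(size)]),
            carriers,
            note,
        )

    def del_1bp_planted(self, locus, carriers, idx=15, name=None, note=""):
        """Single-base deletion at a planted GAT codon (no homopolymer run)."""
        f = self.loci[locus]
        pos = f.start + idx * 3 + 1 if f.strand == "+" else f.end - (idx * 3 + 1)
        self.add(
            name or f"del1_{locus}",
            _mut("DEL", f.replicon_id, pos, ["1"]),
            carriers,
            note,
        )

    def del_homopolymer(self, locus, carriers, run_codon=20, name=None, note=""):
        """1-bp deletion inside the poly-C tract planted at codons 20-21."""
        f = self.loci[locus]
        pos = (
            f.start + run_codon * 3 + 1
            if f.strand == "+"
            else f.end - (run_codon * 3 + 1)
        )
        self.add(
            name or f"hp_del_{locus}",
            _mut("DEL", f.replicon_id, pos, ["1"]),
            carriers,
            note,
        )

    def dup6_in_gene(self, locus, carriers, name=None, note=""):
        """6-bp in-frame duplication of the planted codons 30-31 (GCTGCA)."""
        f = self.loci[locus]
        if f.strand != "+":
            raise ValueError("duplication host genes are laid out on + strand")
        pos = f.start + 32 * 3 - 1  # after last base of codon 31
        self.add(
            name or f"dup6_{locus}",
            _mut("INS", f.replicon_id, pos, ["GCTGCA"]),
            carriers,
            note,
        )

    def gene_deletion(self, locus, carriers, name=None, note=""):
        f = self.loci[locus]
        self.add(
            name or f"gene_del_{locus}",
            _mut("DEL", f.replicon_id, f.start - 10, [str(f.length + 20)]),
            carriers,
            note,
        )

    def replicon_loss(self, rid, carriers, name=None, note=""):
        # Size filled at materialization time (replicon length not final yet).
        self.pending.append(("replicon_loss", name or f"loss_{rid}", rid, carriers, note))

    def substitution(self, locus, carriers, size=30, name=None, note=""):
        f = self.loci[locus]
        new = ("ACGTG" * 6)[:size]
        self.add(
            name or f"sub_{locus}",
            _mut("SUB", f.replicon_id, f.start + 45, [str(size), new]),
            carriers,
            note,
        )

    def intergenic_snp(self, after_locus, carriers, offset=40, name=None, note=""):
        rid, spacer_start = self._spacer_marks[after_locus]
        self.pending.append(
            ("snp_auto", name or f"ig_snp_{after_locus}_{offset}", rid, spacer_start + offset, carriers, note)
        )

    def intergenic_ins1(self, after_locus, carriers, offset=40, name=None, note=""):
        rid, spacer_start = self._spacer_marks[after_locus]
        self.pending.append(
            ("ins_auto", name or f"ig_ins_{after_locus}_{offset}", rid, spacer_start + offset, carriers, note)
        )

    def intergenic_del1(self, after_locus, carriers, offset=40, name=None, note=""):
        rid, spacer_start = self._spacer_marks[after_locus]
        self.add(
            name or f"ig_del_{after_locus}_{offset}",
            _mut("DEL", rid, spacer_start + offset, ["1"]),
            carriers,
            note,
        )

    def intergenic_mob(self, after_locus, carriers, element="ISH27", offset=60, name=None, note=""):
        rid, spacer_start = self._spacer_marks[after_locus]
        self.add(
            name or f"mob_{after_locus}",
            _mut("MOB", rid, spacer_start + offset, [element, "1", "4"]),
            carriers,
            note,
        )

    # --- finalization -------------------------------------------------------

    def finish(
        self,
        manifest: StrainManifest,
        graph: LineageGraph,
        exclude_strains=frozenset(),
        noise_strains=(),
    ) -> StudyScenario:
        genome = Genome({rid: b.sequence for rid, b in self.builders.items()})
        for item in self.pending:
            if item[0] == "replicon_loss":
                _, name, rid, carriers, note = item
                self.add(
                    name,
                    _mut("DEL", rid, 1, [str(len(genome[rid]))]),
                    carriers,
                    note,
                )
            elif item[0] == "snp_auto":
                _, name, rid, pos, carriers, note = item
                ref = genome[rid][pos - 1]
                new = "A" if ref != "A" else "C"
                self.add(name, _mut("SNP", rid, pos, [new]), carriers, note)
            elif item[0] == "ins_auto":
                _, name, rid, pos, carriers, note = item
                ref = genome[rid][pos - 1]
                new = "A" if ref != "A" else "C"
                self.add(name, _mut("INS", rid, pos, [new]), carriers, note)
        features = FeatureIndex(
            [f for b in self.builders.values() for f in b.features]
        )
        # Intended edits become GD records in every carrying strain's file.
        for info in manifest.strains.values():
            if not info.intended_edits:
                continue
            carriers = graph.sequenced_descendants(info.strain_id)
            if not carriers:
                continue
            for e in info.intended_edits:
                name = f"intended_{info.strain_id}_{e.kind}_{e.locus_tag or e.replicon}"
                if e.kind == "gene_deletion":
                    f = self.loci[e.locus_tag]
                    rec = _mut("DEL", f.replicon_id, f.start - 10, [str(f.length + 20)])
                elif e.kind == "replicon_loss":
                    rec = _mut("DEL", e.replicon, 1, [str(len(genome[e.replicon]))])
                elif e.kind == "substitution":
                    f = self.loci[e.locus_tag]
                    rec = _mut("SUB", f.replicon_id, f.start + 45, ["30", ("ACGTG" * 6)[:30]])
                else:
                    raise ValueError(f"unsupported intended edit kind {e.kind}")
                self.add(name, rec, carriers, note="intended")
        return StudyScenario(
            species=self.species,
            genome=genome,
            features=features,
            manifest=manifest,
            graph=graph,
            mutations=self.mutations,
            exclude_strains=frozenset(exclude_strains),
            noise_strains=tuple(noise_strains),
        )


def _make_graph(nodes: list[tuple], edges: list[tuple]) -> tuple[LineageGraph, dict]:
    """nodes: (id, role, sequenced, lab); edges: (parent, child, type)."""
    g = nx.DiGraph()
    node_info = {}
    for nid, role, sequenced, lab in nodes:
        g.add_node(nid, role=role, sequenced=sequenced, lab=lab)
        node_info[nid] = (role, sequenced, lab)
    for parent, child, etype in edges:
        g.add_edge(parent, child, type=etype)
    return LineageGraph(g), node_info


def _manifest(graph: LineageGraph, node_info, intended: dict[str, list[IntendedEdit]]) -> StrainManifest:
    strains = {}
    for nid, (role, sequenced, lab) in node_info.items():
        preds = list(graph.graph.predecessors(nid))
        strains[nid] = StrainInfo(
            strain_id=nid,
            parent_id=preds[0] if preds else None,
            role=role,
            sequenced=sequenced,
            lab=lab,
            intended_edits=tuple(intended.get(nid, ())),
        )
    return StrainManifest(strains)


# Planted-codon kits for each SNP design (0-based codon index -> codon).
_NONSYN = lambda idx=10: {idx: "GCT"}
_SYN = lambda idx=10: {idx: "GGC"}
_S2R = lambda idx=10: {idx: "AGC"}
_L2P = lambda idx=10: {idx: "CTG"}
_DEL1 = lambda idx=15: {idx: "GAT"}
_HP = {19: "GAT", 20: "CCC", 21: "CCC", 22: "CAT"}  # 7-base poly-C tract
_DUP = {30: "GCT", 31: "GCA"}


def _merge(*dicts):
    out = {}
    for d in dicts:
        out.update(d)
    return out


# ---------------------------------------------------------------------------
# Halobacterium salinarum NRC-1 panel


_HBT_BALIGA_KOS = [
    "kaiC", "sirR", "idr1", "idr2", "phoU", "cspD1", "trh2",
    "trh3", "trh4", "trh5", "birA", "hlx1", "hlx2",
]
_HBT_2014_KOS = ["hpyA", "mc1", "cdrS", "ftsZ2"]


def build_hbt_panel(seed: int = 0) -> StudyScenario:
    """The *Hbt. salinarum* panel: 22 sequenced strains, 25 curated mutations.

    11 mutations shared by every strain (six in the mobilome, three
    homopolymer-tract single-base deletions, one intergenic insertion, one
    nonsynonymous SNP); 6 in the Δura3 parental lineage (one the intended
    ura3 deletion, one an IS-element deletion, three nonsynonymous SNPs,
    and a 7-bp frameshift deletion private to the 2014 stock transfer); and
    8 unexpected knockout-strain mutations across 6 of the 19 knockouts.
    """
    p = _PanelBuilder("Hbt. salinarum NRC-1", seed)

    chrom = p.replicon("chromosome")
    # Class I hosts.
    f_is5 = p.gene(chrom, "VNG_RS00125", "IS5 family transposase", 150, "+",
                   overrides=_merge(_NONSYN(10), _NONSYN(20), _NONSYN(30), _NONSYN(40)))
    p.gene(chrom, "VNG_0059H", "IS4-like element ISH8B family transposase", 120, "+")
    p.gene(chrom, "VNG_1587H", "IS5-like element ISH11 family transposase", 120, "-")
    p.gene(chrom, "VNG_1374G", "PAS domain S-box sensor protein", 150, "-", overrides=_S2R(12))
    p.gene(chrom, "VNG_1651H", "hypothetical protein", 100, "+")
    p.gene(chrom, "VNG_1653H", "hypothetical protein", 100, "+")
    p.gene(chrom, "VNG_2662H", "hypothetical protein", 130, "+", overrides=dict(_HP))
    p.gene(chrom, "VNG_0258", "pseudogene fragment", 90, "+", kind="pseudogene", overrides=dict(_HP))
    p.gene(chrom, "VNG_1775", "pseudogene fragment", 90, "+", kind="pseudogene", overrides=dict(_HP))
    # Class II hosts.
    p.gene(chrom, "ura3", "orotidine-5'-phosphate decarboxylase", 140, "+")
    p.gene(chrom, "VNG_RS00465", "ISH3-like element ISH27-2 family transposase", 120, "+")
    p.gene(chrom, "trpB", "tryptophan synthase subunit beta", 160, "+", overrides=_NONSYN(11))
    p.gene(chrom, "gyrB", "DNA gyrase subunit B", 180, "-", overrides=_NONSYN(14))
    p.gene(chrom, "VNG_1896C", "ATP-binding protein", 150, "+")
    # Class III hosts.
    p.gene(chrom, "VNG_2183H", "hypothetical protein", 140, "+", overrides=_NONSYN(13))
    p.gene(chrom, "VNG_1026H", "hypothetical protein", 140, "+", overrides=dict(_DUP))
    p.gene(chrom, "VNG_0597H", "hypothetical protein", 160, "+")
    p.gene(chrom, "nadA", "quinolinate synthase NadA", 150, "+")
    p.gene(chrom, "lrp", "Lrp family transcriptional regulator", 150, "-", overrides=_NONSYN(16))
    p.gene(chrom, "VNG_1213G", "glutamate dehydrogenase", 150, "+", overrides=_SYN(12))
    p.gene(chrom, "VNG_0775H", "hypothetical protein", 110, "+")
    # Knockout target genes.
    for ko in _HBT_BALIGA_KOS + _HBT_2014_KOS + ["rosR"]:
        p.gene(chrom, ko, "transcriptional regulator", 130, "+")

    pnrc100 = p.replicon("pNRC100")
    for i in range(4):
        p.gene(pnrc100, f"VNG_51{i:02d}H", "hypothetical protein", 100, "+")
    pnrc200 = p.replicon("pNRC200")
    p.gene(pnrc200, "VNG_6283H", "hypothetical protein", 140, "+", overrides=_NONSYN(12))
    for i in range(4):
        p.gene(pnrc200, f"VNG_62{i:02d}H", "hypothetical protein", 100, "+")

    # Lineage: NRC-1 reference -> Baliga lab wild type and Δura3 lineages.
    nodes = [
        ("NRC1_ref", "wild_type", False, "reference"),
        ("NRC1_NB", "wild_type", False, "Baliga"),
        ("NRC1_AKS", "wild_type", True, "Schmid"),
        ("Dura3", "parental", False, "origin"),
        ("Dura3_NB", "parental", False, "Baliga"),
        ("Dura3_AKS_2014", "parental", True, "Schmid"),
        ("Dura3_AKS_2017", "parental", True, "Schmid"),
    ]
    edges = [
        ("NRC1_ref", "NRC1_NB", "transfer"),
        ("NRC1_NB", "NRC1_AKS", "transfer"),
        ("NRC1_ref", "Dura3", "manipulation"),
        ("Dura3", "Dura3_NB", "transfer"),
        ("Dura3_NB", "Dura3_AKS_2014", "transfer"),
        ("Dura3_NB", "Dura3_AKS_2017", "transfer"),
    ]
    intended: dict[str, list[IntendedEdit]] = {
        "Dura3": [IntendedEdit(kind="gene_deletion", locus_tag="ura3")]
    }
    for ko in _HBT_BALIGA_KOS:
        nodes.append((f"d_{ko}", "knockout", True, "Baliga"))
        edges.append(("Dura3_NB", f"d_{ko}", "manipulation"))
        intended[f"d_{ko}"] = [IntendedEdit(kind="gene_deletion", locus_tag=ko)]
    for ko in _HBT_2014_KOS:
        nodes.append((f"d_{ko}", "knockout", True, "Schmid"))
        edges.append(("Dura3_AKS_2014", f"d_{ko}", "manipulation"))
        intended[f"d_{ko}"] = [IntendedEdit(kind="gene_deletion", locus_tag=ko)]
    nodes.append(("d_hpyA_mc1", "knockout", True, "Schmid"))
    edges.append(("d_hpyA", "d_hpyA_mc1", "manipulation"))
    intended["d_hpyA_mc1"] = [IntendedEdit(kind="gene_deletion", locus_tag="mc1")]
    nodes.append(("d_rosR", "knockout", True, "Schmid"))
    edges.append(("Dura3_AKS_2017", "d_rosR", "manipulation"))
    intended["d_rosR"] = [IntendedEdit(kind="gene_deletion", locus_tag="rosR")]

    graph, node_info = _make_graph(nodes, edges)
    manifest = _manifest(graph, node_info, intended)

    ALL = graph.sequenced
    ura3_clade = graph.sequenced_descendants("Dura3")
    aks2014_clade = graph.sequenced_descendants("Dura3_AKS_2014")

    # Class I: shared by every sequenced strain.
    p.snp_nonsyn("VNG_RS00125", ALL, idx=10)
    p.snp_nonsyn("VNG_RS00125", ALL, idx=20)
    p.snp_nonsyn("VNG_RS00125", ALL, idx=30)
    p.snp_nonsyn("VNG_RS00125", ALL, idx=40)
    p.gene_deletion("VNG_0059H", ALL, note="ISH8B element excision")
    p.gene_deletion("VNG_1587H", ALL, note="ISH11 element excision")
    p.snp_s2r("VNG_1374G", ALL, idx=12)
    p.intergenic_ins1("VNG_1651H", ALL, offset=55)
    p.del_homopolymer("VNG_2662H", ALL, note="poly-C tract, likely sequencing error")
    p.del_homopolymer("VNG_0258", ALL, note="poly-C tract, likely sequencing error")
    p.del_homopolymer("VNG_1775", ALL, note="poly-C tract, likely sequencing error")

    # Class II: Δura3 lineage (intended ura3 deletion arrives via manifest).
    p.gene_deletion("VNG_RS00465", ura3_clade, note="ISH27-2 transposase deletion")
    p.snp_nonsyn("trpB", ura3_clade, idx=11)
    p.snp_nonsyn("gyrB", ura3_clade, idx=14)
    p.snp_nonsyn("VNG_6283H", ura3_clade, idx=12)
    p.del_in_gene("VNG_1896C", aks2014_clade, size=7, offset=40,
                  note="frameshift fixed during 2014 stock transfer")

    # Class III: unexpected knockout-strain mutations (8 across 6 strains).
    p.snp_nonsyn("VNG_2183H", {"d_cdrS"}, idx=13)
    p.dup6_in_gene("VNG_1026H", {"d_ftsZ2"})
    p.del_in_gene("VNG_0597H", {"d_kaiC"}, size=87, offset=60)
    p.snp_start_loss("nadA", {"d_sirR"})
    p.snp_nonsyn("lrp", {"d_idr1"}, idx=16)
    p.replicon_loss("pNRC100", {"d_idr1"})
    p.snp_syn("VNG_1213G", {"d_mc1"}, idx=12)
    p.intergenic_snp("VNG_0775H", {"d_mc1"}, offset=35)

    return p.finish(
        manifest, graph, noise_strains=("NRC1_AKS", "d_kaiC")
    )


# ---------------------------------------------------------------------------
# Haloferax volcanii DS2 panel


_HFX_SCHMID_KOS = [
    "trmB", "tbsP", "glpR", "kdgR", "rosR2", "sufR",
    "troR", "zur", "cspD2", "arlR", "oapR", "phoB",
]
_HFX_JMF_KOS = [
    "ubaA", "samp1", "samp2", "samp3", "panM", "hst1",
    "hst2", "sirT2", "pan1", "pan2", "pan3",
]
_HFX_AM_KOS = ["trh7", "tfb9", "tfb12", "arcR14", "arcR21", "lsm1"]
_HFX_PS_KOS = ["kdgK1", "gapII"]


def build_hfx_panel(seed: int = 0) -> StudyScenario:
    """The *Hfx. volcanii* panel: 39 sequenced strains, 84 curated mutations.

    13 mutations shared by every strain; 30 in parental lineages (eight of
    them intended: the pHV2 curing, the pyrE2/pyrF marker deletions and the
    edits behind the H119/H555/H1209 parentals); and 41 unexpected
    knockout-strain mutations, six of which cluster in HVO_1871 in the
    single H1209-derived knockout and trace back to its parent's
    construction — that strain is therefore excluded from per-strain
    statistics (but not from classification).
    """
    p = _PanelBuilder("Hfx. volcanii DS2", seed)

    chrom = p.replicon("chromosome")
    # Class I hosts.
    p.gene(chrom, "HVO_2547", "50S ribosomal protein L14", 130, "+", overrides=_L2P(12))
    p.gene(chrom, "HVO_1027", "hypothetical protein", 100, "+")
    p.gene(chrom, "HVO_1028", "hypothetical protein", 100, "+")
    p.gene(chrom, "HVO_3045", "hypothetical protein", 100, "-")
    p.gene(chrom, "HVO_1878", "hypothetical protein", 100, "+")
    p.gene(chrom, "HVO_0712", "shikimate dehydrogenase", 160, "+",
           overrides=_merge(_NONSYN(10), _S2R(31)))
    p.gene(chrom, "HVO_0938", "universal stress protein", 140, "-",
           overrides=_merge(_NONSYN(10), _NONSYN(13)))
    # Class II hosts.
    p.gene(chrom, "HVO_0032", "hypothetical protein", 130, "+", overrides=_NONSYN(10))
    p.gene(chrom, "HVO_1080", "hypothetical protein", 130, "-", overrides=_NONSYN(10))
    p.gene(chrom, "pyrE2", "orotate phosphoribosyltransferase", 140, "+")
    p.gene(chrom, "pyrF", "orotidine-5'-phosphate decarboxylase", 140, "+")
    p.gene(chrom, "ldpA", "dihydrolipoyl dehydrogenase", 150, "+", overrides=_NONSYN(12))
    p.gene(chrom, "HVO_2576", "J-domain-containing protein", 150, "+", overrides=_DEL1(15))
    p.gene(chrom, "HVO_2044", "hypothetical protein", 130, "+", overrides=_NONSYN(10))
    p.gene(chrom, "HVO_1422", "hypothetical protein", 140, "+")
    p.gene(chrom, "trpA", "tryptophan synthase subunit alpha", 150, "+")
    p.gene(chrom, "hdrB", "dihydrofolate reductase", 130, "+")
    p.gene(chrom, "mrr", "Mrr family restriction endonuclease", 140, "+")
    p.gene(chrom, "pitA", "chimeric PitA protein", 160, "+", spacer=260)
    p.gene(chrom, "leuB", "3-isopropylmalate dehydrogenase", 150, "+")
    p.gene(chrom, "HVO_0123", "ABC transporter ATP-binding protein", 140, "+", overrides=_NONSYN(10))
    p.gene(chrom, "HVO_0456", "MFS transporter", 140, "-", overrides=_NONSYN(10))
    p.gene(chrom, "HVO_0789", "glycosyltransferase", 140, "+", overrides=_NONSYN(10))
    p.gene(chrom, "HVO_1011", "ArsR family transcriptional regulator", 130, "+", overrides=_NONSYN(10))
    p.gene(chrom, "HVO_0714", "calcium/sodium antiporter", 150, "+", overrides=_NONSYN(10))
    p.gene(chrom, "HVO_2288", "thermosome subunit", 150, "+", overrides=_SYN(11))
    p.gene(chrom, "HVO_1555", "aconitase", 160, "+", overrides=_SYN(11))
    p.gene(chrom, "HVO_2833", "phosphoglycerate kinase", 150, "-", overrides=_SYN(11))
    p.gene(chrom, "HVO_1900", "hypothetical protein", 110, "+")
    p.gene(chrom, "HVO_0599", "hypothetical protein", 130, "+", overrides=_NONSYN(10))
    p.gene(chrom, "HVO_2722", "hypothetical protein", 130, "-", overrides=_NONSYN(10))
    # Class III hosts.
    p.gene(chrom, "HVO_1871", "hypothetical protein", 160, "+",
           overrides=_merge(_NONSYN(10), _NONSYN(22), _SYN(34), _DEL1(46)))
    p.gene(chrom, "HVO_3322", "branched-chain amino acid aminotransferase", 140, "+", overrides=_NONSYN(10))
    p.gene(chrom, "HVO_3367", "sodium/proline symporter", 150, "+")
    p.gene(chrom, "HVO_0841", "proteasome-activating nucleotidase", 140, "-", overrides=_NONSYN(10))
    p.gene(chrom, "HVO_1643", "transcription initiation factor B", 140, "+", overrides=_NONSYN(10))
    p.gene(chrom, "HVO_2114", "2-keto-3-deoxygluconate kinase", 150, "+")
    p.gene(chrom, "HVO_2558", "ubiquitin-like small archaeal modifier", 120, "+", overrides=_NONSYN(10))
    p.gene(chrom, "HVO_0277", "sugar ABC transporter permease", 150, "+")
    p.gene(chrom, "HVO_1990", "bacterio-opsin activator domain protein", 140, "+", overrides=_NONSYN(10))
    p.gene(chrom, "HVO_0330", "ribosomal protein S4", 130, "+", overrides=_SYN(11))
    p.gene(chrom, "HVO_0650", "citrate synthase", 150, "+", overrides=_SYN(11))
    p.gene(chrom, "HVO_0971", "malate dehydrogenase", 140, "-", overrides=_SYN(11))
    p.gene(chrom, "HVO_1305", "enolase", 150, "+", overrides=_SYN(11))
    p.gene(chrom, "HVO_2471", "fructose-bisphosphate aldolase", 140, "+", overrides=_SYN(11))
    p.gene(chrom, "HVO_2690", "triosephosphate isomerase", 130, "+", overrides=_SYN(11))
    # Knockout target genes.
    for ko in _HFX_SCHMID_KOS + _HFX_JMF_KOS + _HFX_AM_KOS + _HFX_PS_KOS + ["cetZ1"]:
        p.gene(chrom, ko, "transcriptional regulator", 130, "+")

    phv1 = p.replicon("pHV1")
    for i in range(3):
        p.gene(phv1, f"HVO_C00{i}", "hypothetical protein", 100, "+")
    phv2 = p.replicon("pHV2")
    for i in range(2):
        p.gene(phv2, f"HVO_D00{i}", "hypothetical protein", 90, "+")
    phv3 = p.replicon("pHV3")
    p.gene(phv3, "HVO_B0310", "hypothetical protein", 110, "+", spacer=220)
    p.gene(phv3, "HVO_B0311", "XdhC/CoxL family protein", 160, "+",
           overrides=_merge(_NONSYN(10), _NONSYN(25)))
    for i in range(2):
        p.gene(phv3, f"HVO_B04{i:02d}", "hypothetical protein", 100, "+")
    phv4 = p.replicon("pHV4")
    p.gene(phv4, "HVO_A0408", "ISH3 family transposase", 130, "+", overrides=_DEL1(15))
    p.gene(phv4, "HVO_A0634", "metallopeptidase", 150, "+", overrides=_NONSYN(10))
    for i in range(2):
        p.gene(phv4, f"HVO_A07{i:02d}", "hypothetical protein", 100, "+")

    # Lineage.
    nodes = [
        ("DS2_ref", "wild_type", False, "reference"),
        ("DS2_AB", "wild_type", True, "Bisson"),
        ("DS70", "parental", False, "DyallSmith"),
        ("DS70_CD", "parental", False, "Daniels"),
        ("DpyrF_CD", "parental", True, "Daniels"),
        ("H26_TA", "parental", False, "Allers"),
        ("H26_AKS", "parental", True, "Schmid"),
        ("H26_JMF", "parental", True, "MaupinFurlow"),
        ("H119_TA", "parental", False, "Allers"),
        ("H119_AM", "parental", False, "Marchfelder"),
        ("H555_TA", "parental", False, "Allers"),
        ("H555_PS", "parental", False, "Schoenheit"),
        ("H1209_TA", "parental", False, "Allers"),
        ("H1209_RP", "parental", True, "Peck"),
    ]
    edges = [
        ("DS2_ref", "DS2_AB", "transfer"),
        ("DS2_ref", "DS70", "manipulation"),
        ("DS70", "DS70_CD", "transfer"),
        ("DS70_CD", "DpyrF_CD", "manipulation"),
        ("DS70", "H26_TA", "manipulation"),
        ("H26_TA", "H26_AKS", "transfer"),
        ("H26_TA", "H26_JMF", "transfer"),
        ("H26_TA", "H119_TA", "manipulation"),
        ("H119_TA", "H119_AM", "transfer"),
        ("H119_TA", "H555_TA", "manipulation"),
        ("H555_TA", "H555_PS", "transfer"),
        ("H119_TA", "H1209_TA", "manipulation"),
        ("H1209_TA", "H1209_RP", "transfer"),
    ]
    intended: dict[str, list[IntendedEdit]] = {
        "DS70": [IntendedEdit(kind="replicon_loss", replicon="pHV2")],
        "DpyrF_CD": [IntendedEdit(kind="gene_deletion", locus_tag="pyrF")],
        "H26_TA": [IntendedEdit(kind="gene_deletion", locus_tag="pyrE2")],
        "H119_TA": [IntendedEdit(kind="gene_deletion", locus_tag="trpA")],
        "H555_TA": [IntendedEdit(kind="gene_deletion", locus_tag="hdrB")],
        "H1209_TA": [
            IntendedEdit(kind="gene_deletion", locus_tag="mrr"),
            IntendedEdit(kind="substitution", locus_tag="pitA"),
            IntendedEdit(kind="gene_deletion", locus_tag="leuB"),
        ],
    }
    ko_parent = {}
    for ko in _HFX_SCHMID_KOS:
        ko_parent[ko] = "H26_AKS"
    for ko in _HFX_JMF_KOS:
        ko_parent[ko] = "H26_JMF"
    for ko in _HFX_AM_KOS:
        ko_parent[ko] = "H119_AM"
    for ko in _HFX_PS_KOS:
        ko_parent[ko] = "H555_PS"
    ko_parent["cetZ1"] = "H1209_RP"
    lab_of = {
        "H26_AKS": "Schmid", "H26_JMF": "MaupinFurlow", "H119_AM": "Marchfelder",
        "H555_PS": "Schoenheit", "H1209_RP": "Peck",
    }
    for ko, parent in ko_parent.items():
        nodes.append((f"d_{ko}", "knockout", True, lab_of[parent]))
        edges.append((parent, f"d_{ko}", "manipulation"))
        intended[f"d_{ko}"] = [IntendedEdit(kind="gene_deletion", locus_tag=ko)]
    # Double knockouts derived from single knockouts.
    nodes.append(("d_trmB_tbsP", "knockout", True, "Schmid"))
    edges.append(("d_trmB", "d_trmB_tbsP", "manipulation"))
    intended["d_trmB_tbsP"] = [IntendedEdit(kind="gene_deletion", locus_tag="tbsP")]
    nodes.append(("d_glpR_kdgR", "knockout", True, "Schmid"))
    edges.append(("d_glpR", "d_glpR_kdgR", "manipulation"))
    intended["d_glpR_kdgR"] = [IntendedEdit(kind="gene_deletion", locus_tag="kdgR")]

    graph, node_info = _make_graph(nodes, edges)
    manifest = _manifest(graph, node_info, intended)

    ALL = graph.sequenced
    ds70_clade = graph.sequenced_descendants("DS70")
    h119_am_clade = graph.sequenced_descendants("H119_AM")
    h1209_clade = graph.sequenced_descendants("H1209_TA")

    # Class I: shared by every sequenced strain (13).
    p.snp_l2p("HVO_2547", ALL, idx=12, note="reference-genome error at a ribosomal protein")
    p.intergenic_ins1("HVO_1027", ALL, offset=45)
    p.intergenic_ins1("HVO_3045", ALL, offset=45)
    p.del_1bp_planted("HVO_A0408", ALL, idx=15, note="within ISH3 family transposase")
    p.intergenic_snp("HVO_B0310", ALL, offset=150, note="upstream of HVO_B0311")
    p.intergenic_snp("HVO_B0310", ALL, offset=190, note="upstream of HVO_B0311")
    p.intergenic_ins1("HVO_B0310", ALL, offset=120, note="upstream of HVO_B0311")
    p.snp_nonsyn("HVO_B0311", ALL, idx=10)
    p.snp_nonsyn("HVO_B0311", ALL, idx=25)
    p.snp_nonsyn("HVO_0712", ALL, idx=10)
    p.snp_s2r("HVO_0712", ALL, idx=31, note="64 bp from the first HVO_0712 site")
    p.snp_nonsyn("HVO_0938", ALL, idx=10)
    p.snp_nonsyn("HVO_0938", ALL, idx=13, note="9 bp from the first HVO_0938 site")

    # Class II: parental lineages (23 unintended + 7 intended via manifest).
    p.snp_nonsyn("HVO_0032", ds70_clade, idx=10)
    p.snp_nonsyn("HVO_1080", ds70_clade, idx=10)
    p.snp_nonsyn("ldpA", {"DpyrF_CD"}, idx=12)
    p.del_1bp_planted("HVO_2576", {"DpyrF_CD"}, idx=15, note="frameshift")
    p.snp_nonsyn("HVO_2044", {"DpyrF_CD"}, idx=10)
    p.del_in_gene("HVO_1422", {"DpyrF_CD"}, size=9, offset=33)
    p.intergenic_snp("pitA", h1209_clade, offset=60, note="pitA replacement margin")
    p.intergenic_snp("pitA", h1209_clade, offset=95, note="pitA replacement margin")
    p.intergenic_ins1("pitA", h1209_clade, offset=130, note="pitA replacement margin")
    p.intergenic_del1("pitA", h1209_clade, offset=170, note="pitA replacement margin")
    p.snp_nonsyn("HVO_0123", h1209_clade, idx=10)
    p.snp_nonsyn("HVO_0456", h1209_clade, idx=10)
    p.snp_nonsyn("HVO_0789", h1209_clade, idx=10)
    p.snp_nonsyn("HVO_1011", h1209_clade, idx=10)
    p.snp_nonsyn("HVO_A0634", h119_am_clade, idx=10, note="also seen in an H53 intermediate")
    p.snp_nonsyn("HVO_0714", h119_am_clade, idx=10)
    p.snp_syn("HVO_2288", h119_am_clade, idx=11)
    p.snp_syn("HVO_1555", h1209_clade, idx=11)
    p.snp_syn("HVO_2833", h1209_clade, idx=11)
    p.intergenic_snp("HVO_1900", h1209_clade, offset=40, note="read-length dependent call")
    p.snp_nonsyn("HVO_0599", {"H26_AKS"}, idx=10, note="colony-private")
    p.snp_nonsyn("HVO_2722", {"H26_AKS"}, idx=10, note="colony-private")

    # Class III: knockout-strain mutations (41).
    # -- HVO_1871 cluster in the single H1209-derived knockout (6).
    p.snp_nonsyn("HVO_1871", {"d_cetZ1"}, idx=10)
    p.snp_nonsyn("HVO_1871", {"d_cetZ1"}, idx=22)
    p.snp_syn("HVO_1871", {"d_cetZ1"}, idx=34)
    p.del_1bp_planted("HVO_1871", {"d_cetZ1"}, idx=46)
    p.intergenic_snp("HVO_1871", {"d_cetZ1"}, offset=40)
    p.intergenic_snp("HVO_1871", {"d_cetZ1"}, offset=75)
    # -- coding (8).
    p.snp_nonsyn("HVO_3322", {"d_troR"}, idx=10)
    p.del_in_gene("HVO_3367", {"d_troR"}, size=12, offset=36)
    p.snp_nonsyn("HVO_0841", {"d_ubaA"}, idx=10)
    p.snp_nonsyn("HVO_1643", {"d_tfb9"}, idx=10)
    p.del_in_gene("HVO_2114", {"d_kdgK1"}, size=27, offset=45)
    p.snp_nonsyn("HVO_2558", {"d_samp1"}, idx=10)
    p.del_in_gene("HVO_0277", {"d_zur"}, size=10, offset=42, note="frameshift")
    p.snp_nonsyn("HVO_1990", {"d_rosR2"}, idx=10)
    # -- synonymous (6).
    p.snp_syn("HVO_0330", {"d_troR"}, idx=11)
    p.snp_syn("HVO_0650", {"d_ubaA"}, idx=11)
    p.snp_syn("HVO_0971", {"d_panM"}, idx=11)
    p.snp_syn("HVO_1305", {"d_arcR14"}, idx=11)
    p.snp_syn("HVO_2471", {"d_kdgK1"}, idx=11)
    p.snp_syn("HVO_2690", {"d_samp1"}, idx=11)
    # -- noncoding (21).
    p.intergenic_snp("HVO_3322", {"d_troR"}, offset=50)
    p.intergenic_snp("HVO_3367", {"d_troR"}, offset=50)
    p.intergenic_ins1("HVO_0330", {"d_troR"}, offset=60)
    p.intergenic_mob("HVO_0650", {"d_troR"}, element="ISH27", offset=80)
    p.intergenic_snp("HVO_0841", {"d_ubaA"}, offset=50)
    p.intergenic_snp("HVO_0841", {"d_ubaA"}, offset=85)
    p.intergenic_snp("HVO_0650", {"d_ubaA"}, offset=40)
    p.intergenic_snp("HVO_1643", {"d_tfb9"}, offset=50)
    p.intergenic_snp("HVO_1643", {"d_tfb9"}, offset=85)
    p.intergenic_snp("HVO_2114", {"d_kdgK1"}, offset=50)
    p.intergenic_del1("HVO_2558", {"d_samp1"}, offset=55)
    p.intergenic_snp("HVO_1990", {"d_rosR2"}, offset=50)
    p.intergenic_snp("HVO_0971", {"d_panM"}, offset=50)
    p.intergenic_snp("HVO_1305", {"d_arcR14"}, offset=50)
    p.intergenic_ins1("HVO_0277", {"d_zur"}, offset=60)
    p.intergenic_snp("HVO_2471", {"d_tbsP"}, offset=55)
    p.intergenic_snp("HVO_2690", {"d_sufR"}, offset=55)
    p.intergenic_snp("HVO_1871", {"d_hst1"}, offset=110)
    p.intergenic_snp("HVO_2288", {"d_trh7"}, offset=55)
    p.intergenic_snp("HVO_1555", {"d_gapII"}, offset=55)
    p.intergenic_snp("HVO_2833", {"d_glpR", "d_glpR_kdgR"}, offset=55,
                     note="shared by a knockout and its derived double knockout")

    return p.finish(
        manifest,
        graph,
        exclude_strains={"d_cetZ1"},
        noise_strains=("DS2_AB", "d_trmB"),
    )


def build_panels(seed: int = 0) -> dict[str, StudyScenario]:
    """Both species panels keyed by a short species tag."""
    return {"hbt": build_hbt_panel(seed), "hfx": build_hfx_panel(seed)}
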