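"""Synthetic genomes, lineages and GenomeDiff files with ground truth.

Every pipeline stage is testable without downloads: this module generates
(i) genomes with annotated CDSs, IS elements, pseudogenes, homopolymer
tracts and repeat regions; (ii) strain lineage trees with manipulation and
transfer edges, sequenced and unsequenced nodes, parental and knockout
roles; and (iii) per-strain GenomeDiff documents obtained by planting
mutations on lineage edges, so that each sequenced strain's file is the
union of the mutations on its root path plus its inherited intended edits.

The generator emulates the study conditions of a laboratory strain
collection: mutations fixed on lineage edges (point mutations, small
indels, mobile-element events, gene deletions, whole-replicon loss),
reference-error-like mutations shared by all strains, plus three artifact
channels — marginal low-confidence records, repeat-region calls and
homopolymer single-base indels.  Marginal and repeat artifacts (and
evidence-only records) are exactly what the filters remove; homopolymer
artifacts survive filtering and are flagged by annotation instead.

Per-edge mutation counts are Poisson.  The default per-site rate is the
measured background rate for *Haloferax volcanii*, 3.15e-10 per site per
generation; with a per-edge generation count G and genome length L the
per-edge mean is rho * L * G.  Transfers use a lower default mean than
manipulations when fixed means are used instead of a rate: strain
construction involves stronger bottlenecks and selection than passaging.

A fixed seed makes every output byte-identical across runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np

from .annotation import Feature, FeatureIndex, Genome
from .catalog import IntendedEdit, StrainInfo, StrainManifest
from .gd_io import GDDocument, GDEvidence, GDMutation
from .lineage import LineageGraph

#: Background mutation rate (per site per generation) used when simulating
#: from a rate instead of fixed per-edge means.
DEFAULT_RHO = 3.15e-10

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
NONSTOP_CODONS = [c for c in _CODONS if c not in _STOPS]

DEFAULT_TYPE_WEIGHTS = {
    "SNP": 0.55,
    "INS": 0.12,
    "DEL": 0.15,
    "MOB": 0.08,
    "gene_deletion": 0.08,
    "replicon_loss": 0.02,
}


@dataclass
class GenomeSpec:
    """Shape of the synthetic genome."""

    replicon_lengths: tuple[int, ...] = (60_000, 12_000, 8_000)
    n_cds: int = 40
    n_is_elements: int = 4
    n_pseudogenes: int = 2
    n_homopolymer_tracts: int = 6
    homopolymer_run: int = 7
    n_repeat_regions: int = 3
    repeat_region_length: int = 400


@dataclass
class LineageSpec:
    """Shape of the simulated strain lineage."""

    n_parentals: int = 3
    n_knockouts: int = 8
    p_parental_sequenced: float = 0.6
    p_transfer_copy: float = 0.5
    p_double_knockout: float = 0.15
    wild_type_sequenced: bool = True


@dataclass
class SimConfig:
    """Everything the simulator needs; a fixed seed reproduces all outputs."""

    seed: int = 0
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    lineage: LineageSpec = field(default_factory=LineageSpec)
    #: Fixed per-edge Poisson means by edge type (used when rho is None).
    lambda_manipulation: float = 2.0
    lambda_transfer: float = 0.5
    #: Per-site per-generation rate; if set, every edge's mean is
    #: rho * genome_length * generations_per_edge.
    rho: float | None = None
    generations_per_edge: float = 1e4
    type_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_WEIGHTS)
    )
    marginal_rate: float = 0.0
    repeat_artifact_rate: float = 0.0
    homopolymer_artifact_rate: float = 0.0
    evidence_rate: float = 0.0
    intended_edits_per_knockout: int = 1

    def __post_init__(self) -> None:
        total = sum(self.type_weights.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"type weights must sum to 1, got {total}")
        if self.lambda_manipulation < 0 or self.lambda_transfer < 0:
            raise ValueError("per-edge means must be >= 0")


@dataclass
class TruthRecord:
    """Ground truth for one planted mutation (or injected artifact)."""

    mutation_id: str
    template: GDMutation
    #: Earliest lineage edge consistent with the presence pattern (what the
    #: pipeline should recover); None for Class I and artifacts.
    origin_edge: tuple[str, str] | None
    presence: frozenset[str]
    truth_class: str  # I, II, III, unobserved, or "" for artifacts
    intended: bool = False
    artifact_kind: str = ""  # "", marginal, repeat, homopolymer, evidence
    #: The edge the event was actually planted on (may be deeper than the
    #: recoverable origin when intermediate nodes are unsequenced).
    planted_edge: tuple[str, str] | None = None


@dataclass
class SimTruth:
    records: list[TruthRecord]

    def observable(self) -> list[TruthRecord]:
        """Non-artifact mutations visible in at least one sequenced strain."""
        return [
            r
            for r in self.records
            if not r.artifact_kind and r.presence and r.truth_class != "unobserved"
        ]

    def to_tsv(self) -> str:
        lines = ["mutation_id\ttype\treplicon\tposition\tclass\torigin\tintended\tartifact\tpresence"]
        for r in self.records:
            origin = "->".join(r.origin_edge) if r.origin_edge else ""
            lines.append(
                "\t".join(
                    [
                        r.mutation_id,
                        r.template.record_type,
                        r.template.replicon,
                        str(r.template.position),
                        r.truth_class,
                        origin,
                        str(int(r.intended)),
                        r.artifact_kind,
                        ",".join(sorted(r.presence)),
                    ]
                )
            )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Genome construction


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + TAA."""
    body = "".join(
        NONSTOP_CODONS[i]
        for i in rng.integers(0, len(NONSTOP_CODONS), n_codons - 2)
    )
    return "ATG" + body + "TAA"


class RepliconBuilder:
    """Lay out genes, spacers and tracts left to right on one replicon.

    Used both by the random simulator and by curated scenario builders that
    need named genes with designed codons at known coordinates.
    """

    def __init__(self, replicon_id: str, rng: np.random.Generator):
        self.replicon_id = replicon_id
        self.rng = rng
        self.chunks: list[str] = []
        self.pos = 1  # next free 1-based coordinate
        self.features: list[Feature] = []
        self.tracts: list[tuple[int, int]] = []  # (start, end) of homopolymers
        self.repeats: list[tuple[int, int]] = []

    def add_spacer(self, n: int) -> None:
        self.chunks.append(_random_seq(self.rng, n))
        self.pos += n

    def add_homopolymer(self, base: str, run: int, pad: int = 20) -> tuple[int, int]:
        self.add_spacer(pad)
        start = self.pos
        self.chunks.append(base * run)
        self.pos += run
        self.tracts.append((start, self.pos - 1))
        self.add_spacer(pad)
        return start, self.pos - pad - 1

    def add_repeat_region(self, n: int) -> tuple[int, int]:
        start = self.pos
        self.add_spacer(n)
        self.repeats.append((start, self.pos - 1))
        return start, self.pos - 1

    def add_cds(
        self,
        locus_tag: str,
        product: str = "hypothetical protein",
        n_codons: int = 120,
        strand: str = "+",
        kind: str = "CDS",
        codon_overrides: dict[int, str] | None = None,
    ) -> Feature:
        """Append a CDS; ``codon_overrides`` plants specific codons (0-based
        index in the coding frame) so that designed edits are guaranteed to
        find their target context regardless of the seed."""
        cds = _random_cds(self.rng, n_codons)
        for idx, codon in (codon_overrides or {}).items():
            if not 0 < idx < n_codons - 1:
                raise ValueError("can only override internal codons")
            cds = cds[: idx * 3] + codon + cds[idx * 3 + 3 :]
        genomic = cds if strand == "+" else _revcomp(cds)
        start = self.pos
        self.chunks.append(genomic)
        self.pos += len(genomic)
        feature = Feature(
            replicon_id=self.replicon_id,
            start=start,
            end=self.pos - 1,
            strand=strand,
            kind=kind,
            locus_tag=locus_tag,
            product=product,
        )
        self.features.append(feature)
        return feature

    def pad_to(self, length: int) -> None:
        if length > self.pos - 1:
            self.add_spacer(length - (self.pos - 1))

    @property
    def sequence(self) -> str:
        return "".join(self.chunks)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@dataclass
class SyntheticGenome:
    genome: Genome
    features: FeatureIndex
    repeats: dict[str, list[tuple[int, int]]]  # 1-based inclusive intervals
    tracts: dict[str, list[tuple[int, int]]]
    is_locus_tags: list[str]

    def repeat_trees(self):
        from intervaltree import IntervalTree

        trees = {}
        for rep, intervals in self.repeats.items():
            tree = IntervalTree()
            for start, end in intervals:
                tree[start : end + 1] = True
            trees[rep] = tree
        return trees


def make_genome(cfg: SimConfig, rng: np.random.Generator | None = None) -> SyntheticGenome:
    """Generate a genome matching the spec, with recorded tract/repeat sites."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    spec = cfg.genome
    replicon_ids = [
        "chromosome" if i == 0 else f"plasmid_{i}"
        for i in range(len(spec.replicon_lengths))
    ]

    n_rep = len(replicon_ids)
    cds_per_rep = _split_count(spec.n_cds, n_rep)
    is_per_rep = _split_count(spec.n_is_elements, n_rep)
    pseudo_per_rep = _split_count(spec.n_pseudogenes, n_rep)
    tract_per_rep = _split_count(spec.n_homopolymer_tracts, n_rep)
    repeat_per_rep = _split_count(spec.n_repeat_regions, n_rep)

    sequences: dict[str, str] = {}
    features: list[Feature] = []
    repeats: dict[str, list[tuple[int, int]]] = {}
    tracts: dict[str, list[tuple[int, int]]] = {}
    is_tags: list[str] = []
    gene_counter = itertools.count(1)

    for r, (rid, length) in enumerate(zip(replicon_ids, spec.replicon_lengths)):
        b = RepliconBuilder(rid, rng)
        b.add_spacer(100)
        for _ in range(cds_per_rep[r]):
            tag = f"SYN_{next(gene_counter):04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            b.add_cds(tag, "hypothetical protein", int(rng.integers(80, 200)), strand)
            b.add_spacer(int(rng.integers(60, 200)))
        for i in range(is_per_rep[r]):
            tag = f"SYN_{next(gene_counter):04d}"
            family = int(rng.integers(1, 30))
            b.add_cds(tag, f"IS{family} family transposase", 110, "+")
            is_tags.append(tag)
            b.add_spacer(int(rng.integers(60, 200)))
        for _ in range(pseudo_per_rep[r]):
            tag = f"SYN_{next(gene_counter):04d}"
            b.add_cds(tag, "pseudogene fragment", 60, "+", kind="pseudogene")
            b.add_spacer(int(rng.integers(60, 200)))
        for _ in range(tract_per_rep[r]):
            base = "CG"[int(rng.integers(0, 2))]
            b.add_homopolymer(base, spec.homopolymer_run)
        for _ in range(repeat_per_rep[r]):
            b.add_repeat_region(spec.repeat_region_length)
        b.pad_to(length)
        sequences[rid] = b.sequence
        features.extend(b.features)
        repeats[rid] = b.repeats
        tracts[rid] = b.tracts

    return SyntheticGenome(
        genome=Genome(sequences),
        features=FeatureIndex(features),
        repeats=repeats,
        tracts=tracts,
        is_locus_tags=is_tags,
    )


def _split_count(total: int, n: int) -> list[int]:
    base = total // n
    out = [base] * n
    for i in range(total - base * n):
        out[i] += 1
    return out


# ---------------------------------------------------------------------------
# Lineage construction


def make_lineage(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[LineageGraph, StrainManifest]:
    """Random strain lineage tree with roles, edge types and sequenced flags.

    The root is the (unsequenced) reference isolate.  Parentals descend from
    the root or an earlier parental via manipulation edges, optionally with
    a transferred lab copy; knockouts are leaves under random parentals, all
    sequenced; some knockouts gain a derived double knockout.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    spec = cfg.lineage
    g = nx.DiGraph()
    g.add_node("REF", sequenced=False, role="wild_type", lab="origin")
    if spec.wild_type_sequenced:
        g.add_node("WT_LAB", sequenced=True, role="wild_type", lab="lab0")
        g.add_edge("REF", "WT_LAB", type="transfer")

    parentals = []
    for i in range(spec.n_parentals):
        pid = f"P{i + 1}"
        anchor = "REF" if not parentals else str(rng.choice(parentals))
        sequenced = bool(rng.random() < spec.p_parental_sequenced)
        g.add_node(pid, sequenced=sequenced, role="parental", lab=f"lab{i + 1}")
        g.add_edge(anchor, pid, type="manipulation")
        node = pid
        if rng.random() < spec.p_transfer_copy:
            tid = f"{pid}_T"
            g.add_node(
                tid,
                sequenced=bool(rng.random() < spec.p_parental_sequenced),
                role="parental",
                lab=f"lab{i + 1}t",
            )
            g.add_edge(pid, tid, type="transfer")
            node = tid
        parentals.append(node)

    knockouts = []
    for i in range(spec.n_knockouts):
        kid = f"KO{i + 1}"
        parent = str(rng.choice(parentals))
        g.add_node(kid, sequenced=True, role="knockout", lab=g.nodes[parent]["lab"])
        g.add_edge(parent, kid, type="manipulation")
        knockouts.append(kid)
        if rng.random() < spec.p_double_knockout:
            did = f"{kid}x"
            g.add_node(did, sequenced=True, role="knockout", lab=g.nodes[parent]["lab"])
            g.add_edge(kid, did, type="manipulation")
            knockouts.append(did)

    graph = LineageGraph(g)
    strains = {}
    for node, data in g.nodes(data=True):
        preds = list(g.predecessors(node))
        strains[node] = StrainInfo(
            strain_id=node,
            parent_id=preds[0] if preds else None,
            role=data["role"],
            sequenced=data["sequenced"],
            lab=data["lab"],
        )
    return graph, StrainManifest(strains)


# ---------------------------------------------------------------------------
# Mutation planting


class _FootprintRegistry:
    """Keeps planted footprints apart so every planted key is unique."""

    def __init__(self, margin: int = 30):
        self.margin = margin
        self.used: dict[str, list[tuple[int, int]]] = {}

    def try_claim(self, replicon: str, start: int, end: int) -> bool:
        for s, e in self.used.get(replicon, []):
            if start <= e + self.margin and end >= s - self.margin:
                return False
        self.used.setdefault(replicon, []).append((start, end))
        return True


def _brute_force_truth(
    graph: LineageGraph, edge: tuple[str, str]
) -> tuple[frozenset[str], tuple[str, str] | None, str]:
    """Presence, earliest consistent edge and class for a planted edge.

    Straight-line reimplementation of the definitions: presence is the set
    of sequenced strains below the edge; the earliest consistent edge is
    found by walking rootward while the node above still has exactly that
    sequenced-descendant set; the class comes from the deepest such node's
    role.
    """
    presence = graph.sequenced_descendants(edge[1])
    if not presence:
        return presence, None, "unobserved"
    if presence == graph.sequenced:
        return presence, None, "I"
    # Walk down: deepest node whose sequenced descendants equal presence.
    node = edge[1]
    moved = True
    while moved:
        moved = False
        for child in graph.graph.successors(node):
            if graph.sequenced_descendants(child) == presence:
                node = child
                moved = True
                break
    deepest = node
    # Earliest edge (u,v) on the root path with sequenced_descendants(v)
    # equal to presence.
    path = [edge[1]]
    while (p := graph.parent_edge(path[-1])) is not None:
        path.append(p[0])
    origin = None
    for node_up in reversed(path):
        if graph.sequenced_descendants(node_up) == presence:
            origin = graph.parent_edge(node_up)
            break
    truth_class = "III" if graph.role(deepest) == "knockout" else "II"
    return presence, origin, truth_class


def _edge_mean(cfg: SimConfig, genome_length: int, edge_type: str) -> float:
    if cfg.rho is not None:
        return cfg.rho * genome_length * cfg.generations_per_edge
    return cfg.lambda_transfer if edge_type == "transfer" else cfg.lambda_manipulation


def simulate_lineage_mutations(
    cfg: SimConfig,
    syn: SyntheticGenome,
    graph: LineageGraph | None = None,
    manifest: StrainManifest | None = None,
) -> tuple[dict[str, GDDocument], SimTruth, StrainManifest, LineageGraph]:
    """Plant mutations on lineage edges and emit per-strain GD documents.

    Per edge the mutation count is Poisson with the configured mean; types
    follow the mix weights; positions are uniform over permissible sites
    (footprints are kept disjoint so every planted event has a unique
    normalized key).  Each sequenced strain's document contains the
    mutations on its root path plus its inherited intended edits, plus any
    injected artifacts.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    if graph is None or manifest is None:
        graph, manifest = make_lineage(cfg)
    genome = syn.genome
    lengths = genome.lengths
    total_len = sum(lengths.values())
    registry = _FootprintRegistry()
    # Keep lineage mutations clear of repeat regions (those calls would be
    # filtered out) and of homopolymer tracts (reserved for artifacts).
    for rep, intervals in list(syn.repeats.items()) + list(syn.tracts.items()):
        for start, end in intervals:
            registry.try_claim(rep, start, end)
    truth: list[TruthRecord] = []
    mid = itertools.count(1)

    # Intended knockout edits: distinct genes per knockout node.
    available_genes = [
        f
        for f in syn.features.features
        if f.kind == "CDS" and f.locus_tag not in syn.is_locus_tags
    ]
    rng.shuffle(available_genes)
    gene_pool = list(available_genes)
    new_strains = dict(manifest.strains)
    for node in nx.topological_sort(graph.graph):
        if graph.role(node) != "knockout":
            continue
        edits = []
        for _ in range(cfg.intended_edits_per_knockout):
            if not gene_pool:
                break
            target = gene_pool.pop()
            registry.try_claim(target.replicon_id, target.start - 10, target.end + 10)
            edits.append(IntendedEdit(kind="gene_deletion", locus_tag=target.locus_tag))
            template = GDMutation(
                record_type="DEL",
                id="x",
                parent_evidence_ids=[],
                replicon=target.replicon_id,
                position=target.start - 10,
                payload=[str(target.length + 20)],
            )
            parent_edge = graph.parent_edge(node)
            presence, origin, truth_class = _brute_force_truth(graph, parent_edge)
            truth.append(
                TruthRecord(
                    mutation_id=f"m{next(mid)}",
                    template=template,
                    origin_edge=origin,
                    presence=presence,
                    truth_class=truth_class if presence else "unobserved",
                    intended=True,
                    planted_edge=parent_edge,
                )
            )
        info = new_strains[node]
        new_strains[node] = replace(
            info, intended_edits=info.intended_edits + tuple(edits)
        )
    manifest = StrainManifest(new_strains)

    # Decide replicon-loss capacity: non-primary replicons, each lost at most
    # once, only on edges into leaves (so no descendant edge needs the
    # replicon afterwards).
    lossable = [r for r in list(lengths)[1:]]
    edge_list = sorted(graph.graph.edges, key=lambda e: (graph.depth(e[1]), e))

    for edge in edge_list:
        etype = graph.edge_type(edge)
        n = int(rng.poisson(_edge_mean(cfg, total_len, etype)))
        presence, origin, truth_class = _brute_force_truth(graph, edge)
        is_leaf_edge = graph.graph.out_degree(edge[1]) == 0
        for _ in range(n):
            mtype = str(
                rng.choice(list(cfg.type_weights), p=list(cfg.type_weights.values()))
            )
            if mtype == "replicon_loss" and (not lossable or not is_leaf_edge):
                mtype = "DEL"
            template = _plant_mutation(
                mtype, rng, syn, registry, lossable, gene_pool
            )
            if template is None:
                continue
            truth.append(
                TruthRecord(
                    mutation_id=f"m{next(mid)}",
                    template=template,
                    origin_edge=origin,
                    presence=presence,
                    truth_class=truth_class if presence else "unobserved",
                    planted_edge=edge,
                )
            )

    # Artifacts, per sequenced strain.
    artifact_truth: dict[str, list[TruthRecord]] = {s: [] for s in graph.sequenced}
    for strain in sorted(graph.sequenced):
        for _ in range(int(rng.poisson(cfg.marginal_rate))):
            t = _plant_point(rng, syn, registry, attrs={"reject": "FREQUENCY_CUTOFF"})
            if t is not None:
                artifact_truth[strain].append(
                    TruthRecord(
                        f"m{next(mid)}", t, None, frozenset({strain}), "", False, "marginal"
                    )
                )
        for _ in range(int(rng.poisson(cfg.repeat_artifact_rate))):
            t = _plant_in_repeat(rng, syn)
            if t is not None:
                artifact_truth[strain].append(
                    TruthRecord(
                        f"m{next(mid)}", t, None, frozenset({strain}), "", False, "repeat"
                    )
                )
        for _ in range(int(rng.poisson(cfg.homopolymer_artifact_rate))):
            t = _plant_in_tract(rng, syn)
            if t is not None:
                artifact_truth[strain].append(
                    TruthRecord(
                        f"m{next(mid)}", t, None, frozenset({strain}), "", False, "homopolymer"
                    )
                )

    truth.extend(r for rows in artifact_truth.values() for r in rows)

    # Assemble per-strain documents.
    docs: dict[str, GDDocument] = {}
    for strain in sorted(graph.sequenced):
        records = []
        counter = itertools.count(1)
        for rec in truth:
            if rec.artifact_kind and rec.artifact_kind != "evidence":
                continue
            if strain in rec.presence:
                m = rec.template
                records.append(
                    GDMutation(
                        record_type=m.record_type,
                        id=str(next(counter)),
                        parent_evidence_ids=[],
                        replicon=m.replicon,
                        position=m.position,
                        payload=list(m.payload),
                        attributes=dict(m.attributes),
                    )
                )
        for rec in artifact_truth[strain]:
            m = rec.template
            records.append(
                GDMutation(
                    record_type=m.record_type,
                    id=str(next(counter)),
                    parent_evidence_ids=[],
                    replicon=m.replicon,
                    position=m.position,
                    payload=list(m.payload),
                    attributes=dict(m.attributes),
                )
            )
        evidence = []
        for _ in range(int(rng.poisson(cfg.evidence_rate))):
            rep = str(rng.choice(list(lengths)))
            start = int(rng.integers(1, lengths[rep] - 500))
            ev = GDEvidence(
                record_type="UN",
                id=str(next(counter)),
                parent_evidence_ids=[],
                fields=[rep, str(start), str(start + int(rng.integers(50, 400)))],
            )
            evidence.append(ev)
            truth.append(
                TruthRecord(
                    f"m{next(mid)}",
                    GDMutation("SNP", "x", [], rep, start, ["A"]),
                    None,
                    frozenset({strain}),
                    "",
                    False,
                    "evidence",
                )
            )
        docs[strain] = GDDocument(
            metadata=[("GENOME_DIFF", "1.0"), ("TITLE", strain)],
            mutations=records,
            evidence=evidence,
            strain_id=strain,
        )

    # Deduplicate: artifact truth rows already appended per strain above.
    return docs, SimTruth(truth), manifest, graph


def _plant_mutation(mtype, rng, syn, registry, lossable, gene_pool):
    if mtype == "SNP" or mtype == "INS" or mtype == "DEL":
        size = 1
        if mtype == "DEL":
            size = int(rng.integers(1, 20))
        pos_info = _free_position(rng, syn, registry, size)
        if pos_info is None:
            return None
        rep, pos = pos_info
        seq = syn.genome[rep]
        if mtype == "SNP":
            ref = seq[pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            return GDMutation("SNP", "x", [], rep, pos, [alt])
        if mtype == "INS":
            ins = _random_seq(rng, int(rng.integers(1, 9)))
            return GDMutation("INS", "x", [], rep, pos, [ins])
        return GDMutation("DEL", "x", [], rep, pos, [str(size)])
    if mtype == "MOB":
        pos_info = _free_position(rng, syn, registry, 1)
        if pos_info is None:
            return None
        rep, pos = pos_info
        name = f"IS{int(rng.integers(1, 30))}"
        strand = str(rng.choice(["1", "-1"]))
        return GDMutation("MOB", "x", [], rep, pos, [name, strand, str(int(rng.integers(0, 9)))])
    if mtype == "gene_deletion":
        if not gene_pool:
            return None
        target = gene_pool.pop()
        if not registry.try_claim(target.replicon_id, target.start - 5, target.end + 5):
            return None
        return GDMutation(
            "DEL", "x", [], target.replicon_id, target.start - 5, [str(target.length + 10)]
        )
    if mtype == "replicon_loss":
        if not lossable:
            return None
        rep = lossable.pop(int(rng.integers(0, len(lossable))))
        return GDMutation("DEL", "x", [], rep, 1, [str(len(syn.genome[rep]))])
    raise ValueError(f"unknown mutation type {mtype!r}")


def _free_position(rng, syn, registry, size, tries: int = 60):
    lengths = syn.genome.lengths
    reps = list(lengths)
    weights = np.array([lengths[r] for r in reps], dtype=float)
    weights /= weights.sum()
    for _ in range(tries):
        rep = str(rng.choice(reps, p=weights))
        if lengths[rep] <= size + 200:
            continue
        pos = int(rng.integers(100, lengths[rep] - size - 100))
        if registry.try_claim(rep, pos, pos + size - 1):
            return rep, pos
    return None


def _plant_point(rng, syn, registry, attrs):
    pos_info = _free_position(rng, syn, registry, 1)
    if pos_info is None:
        return None
    rep, pos = pos_info
    ref = syn.genome[rep][pos - 1]
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    return GDMutation("SNP", "x", [], rep, pos, [alt], dict(attrs))


def _plant_in_repeat(rng, syn):
    candidates = [
        (rep, start, end)
        for rep, intervals in syn.repeats.items()
        for start, end in intervals
    ]
    if not candidates:
        return None
    rep, start, end = candidates[int(rng.integers(0, len(candidates)))]
    pos = int(rng.integers(start, end + 1))
    ref = syn.genome[rep][pos - 1]
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    return GDMutation("SNP", "x", [], rep, pos, [alt])


def _plant_in_tract(rng, syn):
    candidates = [
        (rep, start, end)
        for rep, intervals in syn.tracts.items()
        for start, end in intervals
    ]
    if not candidates:
        return None
    rep, start, end = candidates[int(rng.integers(0, len(candidates)))]
    pos = int(rng.integers(start, end + 1))
    return GDMutation("DEL", "x", [], rep, pos, ["1"])


# ---------------------------------------------------------------------------
# File emission


def write_gff3(features: FeatureIndex, genome: Genome, path) -> None:
    lines = ["##gff-version 3"]
    for rid, length in genome.lengths.items():
        lines.append(f"##sequence-region {rid} 1 {length}")
    for i, f in enumerate(
        sorted(features.features, key=lambda f: (f.replicon_id, f.start)), start=1
    ):
        ftype = "pseudogene" if f.kind == "pseudogene" else "CDS"
        attrs = f"ID=f{i};locus_tag={f.locus_tag};product={f.product}"
        lines.append(
            "\t".join(
                [f.replicon_id, "synthetic", ftype, str(f.start), str(f.end), ".", f.strand, "0" if ftype == "CDS" else ".", attrs]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        for rid, seq in genome.replicons.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_bed(repeats: dict[str, list[tuple[int, int]]], path) -> None:
    lines = []
    for rep, intervals in repeats.items():
        for start, end in intervals:  # 1-based inclusive -> 0-based half-open
            lines.append(f"{rep}\t{start - 1}\t{end}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def emit_dataset(cfg: SimConfig, outdir) -> None:
    """Write the full synthetic dataset (FASTA, GFF3, BED, GD dir, YAMLs, truth)."""
    from .gd_io import write_genomediff

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    syn = make_genome(cfg)
    docs, truth, manifest, graph = simulate_lineage_mutations(cfg, syn)
    write_fasta(syn.genome, outdir / "genome.fasta")
    write_gff3(syn.features, syn.genome, outdir / "features.gff3")
    write_bed(syn.repeats, outdir / "repeats.bed")
    gd_dir = outdir / "gd"
    gd_dir.mkdir(exist_ok=True)
    for strain, doc in docs.items():
        (gd_dir / f"{strain}.gd").write_text(write_genomediff(doc))
    (outdir / "manifest.yaml").write_text(manifest.to_yaml())
    (outdir / "lineage.yaml").write_text(graph.to_yaml())
    (outdir / "truth.tsv").write_text(truth.to_tsv())
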