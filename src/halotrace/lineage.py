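"""Strain lineage graph and parsimony placement of mutations.

The lineage of a laboratory strain collection is a curated rooted tree: the
root is the published reference / type strain, nodes are strains (sequenced
or known-but-unsequenced intermediates), and each edge is either a genetic
``manipulation`` (a strain constructed from its parent) or a ``transfer``
(the same strain passaged into another lab).  Only some nodes were
sequenced, so absence of a mutation is evidence only at sequenced nodes;
unsequenced intermediates never contradict a placement.  This is why a
mutation's placement is a *range* of consistent edges, reported in full,
with the origin taken at the earliest (root-most) member.

Each cross-strain mutation is classified by its presence pattern over
sequenced strains:

* Class I — present in every sequenced strain of the species (differs from
  the published reference); origin is recorded as "pre-reference" and not
  adjudicated further (ancestral mutation, reference-isolate private
  mutation and reference assembly error are indistinguishable here).
* Class II — acquired in a parental or wild-type lineage and inherited by
  its derived strains.
* Class III — unique to a specific knockout strain (or to a knockout strain
  and double knockouts derived from it), i.e. acquired during strain
  construction.

Presence patterns that match no edge of the tree are flagged as homoplasy
and left unclassified rather than force-fitted with multi-edge parsimony;
in practice they indicate matrix errors or recurrent events that deserve
eyes.  One curated exception: a mutation private to a sequenced *internal*
parental/wild-type strain (absent from all its sequenced descendants) is
classified as Class II with a ``colony_private`` note — it is most simply
explained as fixed only in the specific colony picked for re-sequencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import yaml

from .catalog import MutationMatrix, MutationKey, StrainManifest

EDGE_TYPES = ("manipulation", "transfer")

#: Sentinel origin for Class I mutations.
PRE_REFERENCE = "pre-reference"

Edge = tuple[str, str]


@dataclass
class LineageGraph:
    """Rooted strain tree with typed edges and per-node sequenced/role flags."""

    graph: nx.DiGraph

    def __post_init__(self) -> None:
        g = self.graph
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("lineage graph contains a cycle")
        roots = [n for n in g.nodes if g.in_degree(n) == 0]
        if len(roots) != 1:
            raise ValueError(f"lineage graph must have exactly one root, got {roots}")
        bad = [n for n in g.nodes if g.in_degree(n) > 1]
        if bad:
            raise ValueError(f"nodes with more than one parent: {bad}")
        for u, v, data in g.edges(data=True):
            if data.get("type") not in EDGE_TYPES:
                raise ValueError(f"edge {u}->{v} has no valid type")
        self._seq_desc_cache: dict[str, frozenset[str]] = {}

    @property
    def root(self) -> str:
        return next(n for n in self.graph.nodes if self.graph.in_degree(n) == 0)

    @property
    def sequenced(self) -> frozenset[str]:
        return frozenset(
            n for n, d in self.graph.nodes(data=True) if d.get("sequenced")
        )

    def role(self, node: str) -> str:
        return self.graph.nodes[node]["role"]

    def edge_type(self, edge: Edge) -> str:
        return self.graph.edges[edge]["type"]

    def parent_edge(self, node: str) -> Edge | None:
        preds = list(self.graph.predecessors(node))
        return (preds[0], node) if preds else None

    def depth(self, node: str) -> int:
        return nx.shortest_path_length(self.graph, self.root, node)

    def sequenced_descendants(self, node: str) -> frozenset[str]:
        """Sequenced strains in the subtree rooted at ``node`` (inclusive)."""
        if node not in self.graph:
            raise KeyError(f"unknown strain {node!r}")
        cached = self._seq_desc_cache.get(node)
        if cached is None:
            reach = nx.descendants(self.graph, node) | {node}
            cached = frozenset(reach & self.sequenced)
            self._seq_desc_cache[node] = cached
        return cached

    @classmethod
    def from_manifest(
        cls, manifest: StrainManifest, edge_types: dict[Edge, str] | None = None
    ) -> "LineageGraph":
        """Build the tree from a strain manifest.

        Edge types default to ``manipulation``; ``edge_types`` overrides
        individual (parent, child) edges (e.g. lab transfers).
        """
        g = nx.DiGraph()
        for s in manifest.strains.values():
            g.add_node(s.strain_id, sequenced=s.sequenced, role=s.role, lab=s.lab)
        for s in manifest.strains.values():
            if s.parent_id is not None:
                etype = (edge_types or {}).get((s.parent_id, s.strain_id), "manipulation")
                g.add_edge(s.parent_id, s.strain_id, type=etype)
        return cls(g)

    @classmethod
    def from_yaml(cls, path) -> "LineageGraph":
        data = yaml.safe_load(Path(path).read_text())
        g = nx.DiGraph()
        for node in data["nodes"]:
            g.add_node(
                node["id"],
                sequenced=bool(node.get("sequenced", False)),
                role=node["role"],
                lab=node.get("lab", ""),
            )
        for edge in data["edges"]:
            g.add_edge(edge["parent"], edge["child"], type=edge["type"])
        return cls(g)

    def to_yaml(self) -> str:
        nodes = [
            {
                "id": n,
                "role": d["role"],
                "sequenced": bool(d.get("sequenced")),
                "lab": d.get("lab", ""),
            }
            for n, d in self.graph.nodes(data=True)
        ]
        edges = [
            {"parent": u, "child": v, "type": d["type"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return yaml.safe_dump({"nodes": nodes, "edges": edges}, sort_keys=False)


@dataclass
class Classification:
    """Class, origin and placement range of one cross-strain mutation."""

    key: MutationKey
    mutation_class: str  # I, II, III, unclassified
    origin_edge: Edge | str | None  # edge tuple, PRE_REFERENCE, or None
    consistent_edge_range: list[Edge] = field(default_factory=list)
    homoplasy: bool = False
    intended: bool = False
    colony_private: bool = False
    activity: str = ""  # parental_generation, transfer, knockout_generation, pre_reference

    def origin_label(self) -> str:
        if isinstance(self.origin_edge, tuple):
            return f"{self.origin_edge[0]}->{self.origin_edge[1]}"
        return str(self.origin_edge or "")


def _activity_for(graph: LineageGraph, edge: Edge) -> str:
    if graph.edge_type(edge) == "transfer":
        return "transfer"
    child_role = graph.role(edge[1])
    return (
        "knockout_generation" if child_role == "knockout" else "parental_generation"
    )


def classify_mutation(
    key: MutationKey,
    presence: set[str] | frozenset[str],
    graph: LineageGraph,
    manifest: StrainManifest,
) -> Classification:
    """Classify one mutation from its presence pattern over sequenced strains.

    The consistency predicate for an edge (u -> v) is that the sequenced
    descendants of v are exactly the strains carrying the mutation: a
    mutation that arose on that edge would be inherited by precisely that
    set, and absence at unsequenced nodes is never informative.  All
    consistent edges form a chain; the origin is the root-most one.
    """
    presence = frozenset(presence)
    if not presence:
        raise ValueError("presence set is empty")
    unknown = presence - graph.sequenced
    if unknown:
        raise ValueError(f"presence contains non-sequenced strains: {sorted(unknown)}")

    if presence == graph.sequenced:
        return Classification(
            key=key,
            mutation_class="I",
            origin_edge=PRE_REFERENCE,
            activity="pre_reference",
        )

    consistent = [
        (u, v)
        for u, v in graph.graph.edges
        if graph.sequenced_descendants(v) == presence
    ]
    consistent.sort(key=lambda e: graph.depth(e[1]))

    if not consistent:
        # Colony-private exception: a sequenced internal parental/wild-type
        # strain carrying a mutation none of its sequenced descendants show.
        if len(presence) == 1:
            (strain,) = presence
            role = graph.role(strain)
            has_seq_desc = graph.sequenced_descendants(strain) != presence
            if role in ("parental", "wild_type") and has_seq_desc:
                edge = graph.parent_edge(strain)
                return Classification(
                    key=key,
                    mutation_class="II",
                    origin_edge=edge,
                    consistent_edge_range=[edge] if edge else [],
                    colony_private=True,
                    activity=_activity_for(graph, edge) if edge else "",
                )
        return Classification(
            key=key,
            mutation_class="unclassified",
            origin_edge=None,
            homoplasy=True,
        )

    origin = consistent[0]
    deepest_node = consistent[-1][1]
    role = graph.role(deepest_node)
    mutation_class = "III" if role == "knockout" else "II"
    return Classification(
        key=key,
        mutation_class=mutation_class,
        origin_edge=origin,
        consistent_edge_range=consistent,
        activity=_activity_for(graph, origin),
    )


def classify_all(
    matrix: MutationMatrix, graph: LineageGraph, manifest: StrainManifest
) -> list[Classification]:
    """Classify every matrix column; intended columns are tagged, not dropped.

    Intended columns (expected marker deletions and knockouts) anchor the
    expected placements and are therefore classified like any other column,
    carrying ``intended=True``.
    """
    matrix_strains = set(matrix.strain_ids)
    if not matrix_strains <= graph.sequenced:
        extra = matrix_strains - graph.sequenced
        raise ValueError(f"matrix strains not sequenced in lineage: {sorted(extra)}")
    out = []
    for label in matrix.key_labels:
        c = classify_mutation(
            matrix.keys[label], matrix.presence(label), graph, manifest
        )
        c.intended = matrix.is_intended(label)
        out.append(c)
    return out


def classifications_tsv(classifications: list[Classification]) -> str:
    lines = [
        "key\tclass\torigin\tactivity\tintended\thomoplasy\tcolony_private\tedge_range"
    ]
    for c in classifications:
        rng = ";".join(f"{u}->{v}" for u, v in c.consistent_edge_range)
        lines.append(
            "\t".join(
                [
                    c.key.label,
                    c.mutation_class,
                    c.origin_label(),
                    c.activity,
                    str(int(c.intended)),
                    str(int(c.homoplasy)),
                    str(int(c.colony_private)),
                    rng,
                ]
            )
        )
    return "\n".join(lines) + "\n"
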