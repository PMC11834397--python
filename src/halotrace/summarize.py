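"""Per-species summary statistics and figure-ready table exports.

The headline numbers of a strain-collection survey: how many mutations fall
in each class, how many unexpected (second-site) mutations each knockout
strain carries, what fraction of knockout strains carry at least one, and
the per-strain density of coding mutations.  Also exports the clustered
presence/absence heatmap ordering and the per-mutation genome-plot table.

Counting conventions (chosen to match how strain surveys are reported):

* Mutation counts count distinct normalized keys (matrix columns), not
  strain incidences — one deletion shared by a knockout and its derived
  double knockout is one mutation.
* Class I and Class II totals include experimenter-intended columns (the
  expected marker deletions are part of the lineage-defining cohort);
  the headline Class III count covers only unintended ("unexpected
  second-site") mutations, which are what knockout verification cares
  about.  Both total and unintended counts are reported for every class.
* A "coding" mutation is one whose effect category alters a protein:
  nonsynonymous, start_loss, nonsense, frameshift, in_frame_indel,
  gene_deletion or replicon_loss.  Synonymous and intergenic changes are
  not coding.
* Per-strain statistics can exclude a configured set of strains (e.g. a
  strain whose calls are dominated by known construction artifacts of its
  parent); class counts always cover the full strain set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .annotation import EffectAnnotation, Genome
from .catalog import MutationMatrix, StrainManifest
from .lineage import Classification

CLASS_RING = {"I": "outer", "II": "middle", "III": "inner"}


@dataclass
class SummaryReport:
    """Per-species counts, densities and tallies."""

    species: str
    n_strains: int
    n_knockout_strains: int
    #: Distinct keys per class, including intended columns.
    class_counts_total: dict[str, int]
    #: Distinct unintended keys per class.
    class_counts_unintended: dict[str, int]
    n_unclassified: int
    #: Unintended Class III keys present in each knockout strain
    #: (analysis set only).
    per_strain_unintended: dict[str, int]
    mean_unintended_per_knockout: float
    max_unintended_per_knockout: int
    fraction_knockouts_with_mutation: float
    coding_mutation_density: float
    effect_category_counts: dict[str, int]
    mobilome_counts: dict[str, int]
    excluded_strains: tuple[str, ...] = ()
    n_analysis_knockouts: int = 0

    @property
    def headline_class_counts(self) -> dict[str, int]:
        """(I total, II total, III unintended) — the conventional report."""
        return {
            "I": self.class_counts_total["I"],
            "II": self.class_counts_total["II"],
            "III": self.class_counts_unintended["III"],
        }

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "n_strains": self.n_strains,
            "n_knockout_strains": self.n_knockout_strains,
            "n_analysis_knockouts": self.n_analysis_knockouts,
            "class_counts_total": self.class_counts_total,
            "class_counts_unintended": self.class_counts_unintended,
            "headline_class_counts": self.headline_class_counts,
            "n_unclassified": self.n_unclassified,
            "per_strain_unintended": self.per_strain_unintended,
            "mean_unintended_per_knockout": self.mean_unintended_per_knockout,
            "max_unintended_per_knockout": self.max_unintended_per_knockout,
            "fraction_knockouts_with_mutation": self.fraction_knockouts_with_mutation,
            "coding_mutation_density": self.coding_mutation_density,
            "effect_category_counts": self.effect_category_counts,
            "mobilome_counts": self.mobilome_counts,
            "excluded_strains": list(self.excluded_strains),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def summarize_species(
    classifications: list[Classification],
    matrix: MutationMatrix,
    manifest: StrainManifest,
    annotations: dict[str, EffectAnnotation] | None = None,
    species: str = "",
    exclude_strains: set[str] | None = None,
) -> SummaryReport:
    """Compute the per-species summary from classified matrix columns.

    ``annotations`` maps key labels to effect annotations; without them the
    coding density and effect tallies are reported as zero counts.
    ``exclude_strains`` removes strains from the per-strain statistics (both
    numerator and denominator); class counts are unaffected.
    """
    if not matrix.strain_ids:
        raise ValueError("empty strain set")
    annotations = annotations or {}
    exclude = set(exclude_strains or ())

    by_label = {c.key.label: c for c in classifications}
    missing = set(matrix.key_labels) - set(by_label)
    if missing:
        raise ValueError(f"classifications missing for {len(missing)} columns")

    class_total = {"I": 0, "II": 0, "III": 0}
    class_unint = {"I": 0, "II": 0, "III": 0}
    n_unclassified = 0
    for c in classifications:
        if c.mutation_class == "unclassified":
            n_unclassified += 1
            continue
        class_total[c.mutation_class] += 1
        if not c.intended:
            class_unint[c.mutation_class] += 1

    knockouts = sorted(
        s.strain_id
        for s in manifest.strains.values()
        if s.role == "knockout" and s.sequenced
    )
    analysis_knockouts = [s for s in knockouts if s not in exclude]

    # Unintended Class III keys restricted to the analysis strain set.
    class3_labels = [
        c.key.label
        for c in classifications
        if c.mutation_class == "III" and not c.intended
    ]
    per_strain = {s: 0 for s in analysis_knockouts}
    analysis_labels = []
    for label in class3_labels:
        carriers = matrix.presence(label) - exclude
        if not carriers:
            continue
        analysis_labels.append(label)
        for s in carriers:
            if s in per_strain:
                per_strain[s] += 1

    n_analysis = len(analysis_knockouts)
    n_unique = len(analysis_labels)
    mean = n_unique / n_analysis if n_analysis else 0.0
    max_per = max(per_strain.values(), default=0)
    frac = (
        sum(1 for v in per_strain.values() if v > 0) / n_analysis if n_analysis else 0.0
    )
    coding_labels = [
        lab
        for lab in analysis_labels
        if lab in annotations and annotations[lab].coding
    ]
    density = len(coding_labels) / n_analysis if n_analysis else 0.0

    effect_counts: dict[str, int] = {}
    mobilome_counts = {"mobilome": 0, "non_mobilome": 0}
    for c in classifications:
        ann = annotations.get(c.key.label)
        if ann is None:
            continue
        effect_counts[ann.category] = effect_counts.get(ann.category, 0) + 1
        mobilome_counts["mobilome" if ann.mobilome else "non_mobilome"] += 1

    return SummaryReport(
        species=species,
        n_strains=len(matrix.strain_ids),
        n_knockout_strains=len(knockouts),
        class_counts_total=class_total,
        class_counts_unintended=class_unint,
        n_unclassified=n_unclassified,
        per_strain_unintended=per_strain,
        mean_unintended_per_knockout=mean,
        max_unintended_per_knockout=max_per,
        fraction_knockouts_with_mutation=frac,
        coding_mutation_density=density,
        effect_category_counts=effect_counts,
        mobilome_counts=mobilome_counts,
        excluded_strains=tuple(sorted(exclude)),
        n_analysis_knockouts=n_analysis,
    )


@dataclass
class HeatmapTable:
    """Clustered ordering of the presence matrix for heatmap rendering."""

    strain_order: list[str]
    key_order: list[str]
    states: pd.DataFrame  # reordered three-state matrix

    def to_tsv(self) -> str:
        return self.states.to_csv(sep="\t")


def _cluster_order(binary: np.ndarray, labels: list[str]) -> list[int]:
    """Leaf order from average-linkage clustering on binary Jaccard distance.

    Rows are pre-sorted by label before computing the linkage so the result
    is invariant to input ordering; ties inside the linkage are broken by
    that canonical order.
    """
    n = binary.shape[0]
    if n <= 1:
        return list(range(n))
    order = sorted(range(n), key=lambda i: labels[i])
    arranged = binary[order]
    dist = pdist(arranged.astype(bool), metric="jaccard")
    dist = np.nan_to_num(dist)  # all-zero rows yield nan distance
    tree = linkage(dist, method="average")
    leaves = leaves_list(tree)
    return [order[i] for i in leaves]


def export_heatmap(matrix: MutationMatrix) -> HeatmapTable:
    """Order strains and mutations by hierarchical clustering on presence.

    Both intended and unintended cells count as present; the metric is
    binary Jaccard distance with average linkage, deterministic given the
    canonical label-sorted input ordering.
    """
    if matrix.states.empty:
        raise ValueError("empty matrix")
    binary = (matrix.states.values > 0).astype(int)
    row_idx = _cluster_order(binary, matrix.strain_ids)
    col_idx = _cluster_order(binary.T, matrix.key_labels)
    strain_order = [matrix.strain_ids[i] for i in row_idx]
    key_order = [matrix.key_labels[i] for i in col_idx]
    return HeatmapTable(
        strain_order=strain_order,
        key_order=key_order,
        states=matrix.states.loc[strain_order, key_order],
    )


def export_genome_plot(
    classifications: list[Classification],
    annotations: dict[str, EffectAnnotation],
    genome: Genome,
) -> pd.DataFrame:
    """One row per classified mutation for a circular genome plot.

    Columns: replicon, start coordinate, class ring (outer=I, middle=II,
    inner=III), effect category, mobilome flag.
    """
    rows = []
    lengths = genome.lengths
    for c in classifications:
        ann = annotations.get(c.key.label)
        pos = c.key.position
        if c.key.replicon in lengths and not (1 <= pos <= lengths[c.key.replicon]):
            raise ValueError(f"{c.key.label}: position outside replicon")
        rows.append(
            {
                "key": c.key.label,
                "replicon": c.key.replicon,
                "start": pos,
                "mutation_class": c.mutation_class,
                "ring": CLASS_RING.get(c.mutation_class, "unplaced"),
                "effect": ann.category if ann else "",
                "mobilome": bool(ann.mobilome) if ann else False,
            }
        )
    columns = ["key", "replicon", "start", "mutation_class", "ring", "effect", "mobilome"]
    return pd.DataFrame(rows, columns=columns)
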