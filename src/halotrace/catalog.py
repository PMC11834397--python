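"""Cross-strain mutation identity: normalized keys, presence matrix, intent flags.

Mutations called independently in different strains against the same
reference must be recognized as the same event before any lineage reasoning
can happen.  Identity is exact on a normalized key: indels are left-aligned
against the reference (so the same homopolymer indel reported at different
offsets collapses to one key), payloads are uppercased, and a deletion
spanning (almost) a whole replicon collapses to a replicon-loss key.

Matching across strains is deliberately exact — calls against a shared
reference make coordinates directly comparable, and positional fuzziness
would silently merge distinct events.  A near-miss report (same replicon,
different key, within 10 bp) is emitted for manual review instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ._seq import left_align_deletion, left_align_insertion
from .annotation import (
    DEFAULT_REPLICON_LOSS_FRACTION,
    CoordinateError,
    FeatureIndex,
    Genome,
)
from .gd_io import GDMutation

ROLES = ("wild_type", "parental", "knockout")


@dataclass(frozen=True)
class MutationKey:
    """Normalized cross-strain identity of one mutation event."""

    replicon: str
    position: int  # 1-based, left-aligned
    kind: str  # SNP, SUB, DEL, INS, MOB, AMP, CON, INV, REPLICON_LOSS
    ref_payload: str = ""
    alt_payload: str = ""
    size: int = 0

    @property
    def end(self) -> int:
        """Last reference base of the footprint (1-based inclusive)."""
        if self.kind in ("DEL", "SUB", "AMP", "CON", "INV", "REPLICON_LOSS"):
            return self.position + max(self.size, 1) - 1
        return self.position

    @property
    def label(self) -> str:
        parts = [self.replicon, str(self.position), self.kind]
        if self.ref_payload:
            parts.append(self.ref_payload if len(self.ref_payload) <= 12 else f"{self.size}bp")
        if self.alt_payload:
            parts.append(self.alt_payload if len(self.alt_payload) <= 12 else f"+{len(self.alt_payload)}bp")
        if self.kind in ("AMP",):
            parts.append(str(self.size))
        return ":".join(parts)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def normalize_mutation(
    m: GDMutation,
    genome: Genome,
    replicon_loss_fraction: float = DEFAULT_REPLICON_LOSS_FRACTION,
) -> MutationKey:
    """Normalize one mutation record to its cross-strain identity key."""
    if m.replicon not in genome:
        raise CoordinateError(f"unknown replicon {m.replicon!r}")
    seq = genome[m.replicon]
    if not (1 <= m.position <= len(seq)) or m.end > len(seq):
        raise CoordinateError(
            f"{m.record_type} at {m.replicon}:{m.position} outside replicon"
        )

    if m.record_type == "SNP":
        ref = seq[m.position - 1]
        return MutationKey(m.replicon, m.position, "SNP", ref, m.new_seq.upper(), 1)

    if m.record_type == "DEL":
        size = m.size
        if size >= replicon_loss_fraction * len(seq):
            return MutationKey(m.replicon, 1, "REPLICON_LOSS", size=len(seq))
        pos = left_align_deletion(seq, m.position, size)
        ref = seq[pos - 1 : pos - 1 + size]
        return MutationKey(m.replicon, pos, "DEL", ref, "", size)

    if m.record_type == "INS":
        pos, inserted = left_align_insertion(seq, m.position, m.new_seq.upper())
        return MutationKey(m.replicon, max(pos, 1), "INS", "", inserted, 0)

    if m.record_type == "SUB":
        ref = seq[m.position - 1 : m.position - 1 + m.size]
        return MutationKey(m.replicon, m.position, "SUB", ref, m.new_seq.upper(), m.size)

    if m.record_type == "MOB":
        repeat_name, strand, dup = m.payload[0], m.payload[1], m.payload[2]
        return MutationKey(
            m.replicon, m.position, "MOB", "", f"{repeat_name.upper()}/{strand}/{dup}", 0
        )

    if m.record_type == "AMP":
        copies = m.payload[1]
        return MutationKey(m.replicon, m.position, "AMP", "", f"x{copies}", m.size)

    # CON / INV: footprint-level identity.
    return MutationKey(m.replicon, m.position, m.record_type, "", "", m.size)


@dataclass(frozen=True)
class IntendedEdit:
    """One experimenter-intended genotype change from the strain manifest."""

    kind: str  # gene_deletion, replicon_loss, substitution, interval
    locus_tag: str = ""
    replicon: str = ""
    start: int = 0
    end: int = 0


@dataclass
class StrainInfo:
    strain_id: str
    parent_id: str | None
    role: str
    sequenced: bool
    lab: str = ""
    intended_edits: tuple[IntendedEdit, ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for {self.strain_id}")


@dataclass
class StrainManifest:
    """All strains of one species, their parentage and intended genotypes."""

    strains: dict[str, StrainInfo]

    def __post_init__(self) -> None:
        for s in self.strains.values():
            if s.parent_id is not None and s.parent_id not in self.strains:
                raise ValueError(
                    f"{s.strain_id} names unknown parent {s.parent_id!r}"
                )

    @property
    def sequenced_ids(self) -> list[str]:
        return [s.strain_id for s in self.strains.values() if s.sequenced]

    def ancestors(self, strain_id: str) -> list[str]:
        """Parent chain from ``strain_id`` (exclusive) up to the root."""
        chain = []
        cur = self.strains[strain_id].parent_id
        while cur is not None:
            chain.append(cur)
            cur = self.strains[cur].parent_id
        return chain

    def inherited_intended_edits(self, strain_id: str) -> list[IntendedEdit]:
        """The strain's own intended edits plus those of every ancestor."""
        edits = list(self.strains[strain_id].intended_edits)
        for anc in self.ancestors(strain_id):
            edits.extend(self.strains[anc].intended_edits)
        return edits

    @classmethod
    def from_yaml(cls, path) -> "StrainManifest":
        data = yaml.safe_load(Path(path).read_text())
        strains = {}
        for entry in data["strains"]:
            edits = tuple(
                IntendedEdit(
                    kind=e["kind"],
                    locus_tag=e.get("locus_tag", ""),
                    replicon=e.get("replicon", ""),
                    start=e.get("start", 0),
                    end=e.get("end", 0),
                )
                for e in entry.get("intended_edits", [])
            )
            strains[entry["id"]] = StrainInfo(
                strain_id=entry["id"],
                parent_id=entry.get("parent"),
                role=entry["role"],
                sequenced=bool(entry.get("sequenced", False)),
                lab=entry.get("lab", ""),
                intended_edits=edits,
            )
        return cls(strains)

    def to_yaml(self) -> str:
        out = {"strains": []}
        for s in self.strains.values():
            entry: dict = {
                "id": s.strain_id,
                "parent": s.parent_id,
                "role": s.role,
                "sequenced": s.sequenced,
                "lab": s.lab,
            }
            if s.intended_edits:
                entry["intended_edits"] = [
                    {
                        k: v
                        for k, v in {
                            "kind": e.kind,
                            "locus_tag": e.locus_tag,
                            "replicon": e.replicon,
                            "start": e.start,
                            "end": e.end,
                        }.items()
                        if v
                    }
                    for e in s.intended_edits
                ]
            out["strains"].append(entry)
        return yaml.safe_dump(out, sort_keys=False)


def key_matches_edit(
    key: MutationKey, edit: IntendedEdit, features: FeatureIndex
) -> bool:
    """Whether a normalized key realizes an intended edit.

    * ``gene_deletion`` — a DEL whose footprint covers the named locus;
    * ``replicon_loss`` — a replicon-loss key on the named replicon;
    * ``substitution`` — a SUB/CON overlapping the named locus (marker or
      allele replacements);
    * ``interval`` — any key whose footprint intersects the given interval.
    """
    if edit.kind == "replicon_loss":
        return key.kind == "REPLICON_LOSS" and key.replicon == edit.replicon
    if edit.kind == "interval":
        return (
            key.replicon == edit.replicon
            and key.position <= edit.end
            and key.end >= edit.start
        )
    target = _locus_feature(features, edit.locus_tag)
    if target is None:
        return False
    if edit.kind == "gene_deletion":
        return (
            key.kind == "DEL"
            and key.replicon == target.replicon_id
            and key.position <= target.start
            and key.end >= target.end
        )
    if edit.kind == "substitution":
        return (
            key.kind in ("SUB", "CON")
            and key.replicon == target.replicon_id
            and key.position <= target.end
            and key.end >= target.start
        )
    raise ValueError(f"unknown intended-edit kind {edit.kind!r}")


def _locus_feature(features: FeatureIndex, locus_tag: str):
    for f in features.features:
        if f.locus_tag == locus_tag:
            return f
    return None


# Cell states of the presence matrix.
ABSENT, PRESENT_UNINTENDED, PRESENT_INTENDED = 0, 1, 2


@dataclass
class MutationMatrix:
    """Strain x mutation presence matrix with three-state cells.

    ``states`` is a DataFrame indexed by sequenced strain id with one column
    per normalized key label; values are 0 (absent), 1 (present, unintended)
    or 2 (present, experimenter-intended for that strain or an ancestor).
    """

    states: pd.DataFrame
    keys: dict[str, MutationKey] = field(default_factory=dict)

    @property
    def strain_ids(self) -> list[str]:
        return list(self.states.index)

    @property
    def key_labels(self) -> list[str]:
        return list(self.states.columns)

    def presence(self, label: str) -> set[str]:
        col = self.states[label]
        return set(col.index[col > 0])

    def intended_in(self, label: str) -> set[str]:
        col = self.states[label]
        return set(col.index[col == PRESENT_INTENDED])

    def is_intended(self, label: str) -> bool:
        """A column is intended if it is intended in every strain carrying it."""
        col = self.states[label]
        carriers = col[col > 0]
        return len(carriers) > 0 and bool((carriers == PRESENT_INTENDED).all())

    def to_tsv(self) -> str:
        return self.states.to_csv(sep="\t")


def build_matrix(
    kept: dict[str, list[GDMutation]],
    manifest: StrainManifest,
    genome: Genome,
    features: FeatureIndex,
    replicon_loss_fraction: float = DEFAULT_REPLICON_LOSS_FRACTION,
) -> MutationMatrix:
    """Build the strain x mutation presence matrix from filtered calls."""
    for strain_id in kept:
        info = manifest.strains.get(strain_id)
        if info is None:
            raise KeyError(f"strain {strain_id!r} missing from manifest")
        if not info.sequenced:
            raise ValueError(f"strain {strain_id!r} is not marked sequenced")

    per_strain_keys: dict[str, set[MutationKey]] = {}
    all_keys: dict[str, MutationKey] = {}
    for strain_id, mutations in kept.items():
        keys = set()
        for m in mutations:
            key = normalize_mutation(m, genome, replicon_loss_fraction)
            keys.add(key)
            all_keys[key.label] = key
        per_strain_keys[strain_id] = keys

    ordered = sorted(
        all_keys.values(),
        key=lambda k: (k.replicon, k.position, k.kind, k.ref_payload, k.alt_payload),
    )
    strains = sorted(kept)
    states = pd.DataFrame(
        ABSENT, index=strains, columns=[k.label for k in ordered], dtype=int
    )
    for strain_id in strains:
        intended = manifest.inherited_intended_edits(strain_id)
        for key in per_strain_keys[strain_id]:
            hit = any(key_matches_edit(key, e, features) for e in intended)
            states.loc[strain_id, key.label] = (
                PRESENT_INTENDED if hit else PRESENT_UNINTENDED
            )
    return MutationMatrix(states=states, keys={k.label: k for k in ordered})


def near_miss_report(matrix: MutationMatrix, max_distance: int = 10) -> list[dict]:
    """Pairs of distinct keys on the same replicon within ``max_distance`` bp.

    These are candidates for the same underlying event called with slightly
    different endpoints in different strains; they are surfaced for manual
    review rather than merged.
    """
    keys = sorted(matrix.keys.values(), key=lambda k: (k.replicon, k.position))
    out = []
    for i, a in enumerate(keys):
        for b in keys[i + 1 :]:
            if b.replicon != a.replicon:
                break
            if b.position - a.end > max_distance:
                break
            out.append(
                {
                    "key_a": a.label,
                    "key_b": b.label,
                    "distance": max(0, b.position - a.end),
                }
            )
    return out
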