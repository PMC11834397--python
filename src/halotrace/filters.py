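"""High-confidence mutation filtering with a full audit ledger.

Only mutations called with high confidence enter the cross-strain analysis.
Three exclusion rules apply, each leaving an auditable trace:

* ``low_confidence`` — mutation records carrying a configured marginal
  marker (``reject``/``marginal`` attributes, or a polymorphism frequency
  below 1), which typically arise from mixed, non-clonal populations;
* ``evidence_only_MC`` / ``evidence_only_JC`` / ``evidence_only_UN`` —
  unassigned missing-coverage, junction and unknown-base evidence records
  are logged but never promoted to mutations (large deletions must arrive
  as explicit DEL mutation records to count);
* ``repeat_region`` — otherwise high-quality calls whose footprint lies
  inside a user-supplied repeat interval, where short-read mapping is
  unreliable (large deletions that merely span a repeat are kept).

Filtering runs before identity normalization so that artifacts never enter
the cross-strain presence matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .annotation import contained_in_repeat
from .gd_io import DEFAULT_MARGINAL_KEYS, GDDocument, GDEvidence, GDMutation

EXCLUSION_REASONS = (
    "low_confidence",
    "evidence_only_MC",
    "evidence_only_JC",
    "evidence_only_UN",
    "repeat_region",
)


@dataclass
class FilterConfig:
    """Which exclusion rules are active and how marginality is detected."""

    marginal_keys: tuple[str, ...] = DEFAULT_MARGINAL_KEYS
    exclude_low_confidence: bool = True
    exclude_repeat_regions: bool = True


@dataclass
class FilterLedger:
    """Outcome of filtering one strain's document: every record accounted for."""

    strain_id: str
    kept: list[GDMutation] = field(default_factory=list)
    excluded: list[tuple[GDMutation | GDEvidence, str]] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        out = {reason: 0 for reason in EXCLUSION_REASONS}
        for _, reason in self.excluded:
            out[reason] += 1
        return out

    @property
    def n_considered(self) -> int:
        return len(self.kept) + len(self.excluded)

    def to_rows(self) -> list[tuple[str, str, str, str]]:
        """(strain, record id, decision, reason) rows for TSV export."""
        rows = [(self.strain_id, m.id, "kept", "") for m in self.kept]
        rows += [(self.strain_id, r.id, "excluded", why) for r, why in self.excluded]
        return rows


def apply_exclusions(
    doc: GDDocument,
    repeats: dict[str, IntervalTree] | None = None,
    cfg: FilterConfig | None = None,
) -> FilterLedger:
    """Apply the exclusion rules to one strain's document.

    Conservation: every mutation record and every excludable (MC/JC/UN)
    evidence record lands in exactly one of ``kept`` or ``excluded``, with a
    single primary reason.  Ordering is deterministic (input order).
    """
    cfg = cfg or FilterConfig()
    repeats = repeats or {}
    ledger = FilterLedger(strain_id=doc.strain_id)

    for m in doc.mutations:
        if cfg.exclude_low_confidence and m.is_marginal(cfg.marginal_keys):
            ledger.excluded.append((m, "low_confidence"))
        elif cfg.exclude_repeat_regions and contained_in_repeat(m, repeats):
            ledger.excluded.append((m, "repeat_region"))
        else:
            ledger.kept.append(m)

    for e in doc.evidence:
        if e.record_type in ("MC", "JC", "UN"):
            ledger.excluded.append((e, f"evidence_only_{e.record_type}"))

    return ledger


def ledger_tsv(ledgers: list[FilterLedger]) -> str:
    """Serialize ledgers as a TSV with a header row."""
    lines = ["strain\trecord_id\tdecision\treason"]
    for ledger in ledgers:
        for row in ledger.to_rows():
            lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
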