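"""Reading and writing GenomeDiff (GD) files.

GenomeDiff is the tab-separated interchange format used by clonal microbial
variant callers to describe the mutational differences between a re-sequenced
sample and its reference genome.  A document begins with a ``#=GENOME_DIFF``
version header, followed by optional ``#=KEY value`` metadata lines and one
record per line.  Mutation records (SNP, SUB, DEL, INS, MOB, AMP, CON, INV)
describe inferred discrete events; evidence records (RA, MC, JC, UN) carry the
read-level support those events were called from.

Coordinates are 1-based inclusive throughout this module (the GD convention);
any conversion to other conventions happens at the boundaries of other
modules.  Unknown record types are retained verbatim rather than rejected, so
documents produced by newer callers still load.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

MUTATION_TYPES = frozenset({"SNP", "SUB", "DEL", "INS", "MOB", "AMP", "CON", "INV"})
EVIDENCE_TYPES = frozenset({"RA", "MC", "JC", "UN"})

#: Number of type-specific positional columns following (type, id, parent_ids).
_MUTATION_COLUMNS = {
    "SNP": 3,  # seq_id, position, new_seq
    "SUB": 4,  # seq_id, position, size, new_seq
    "DEL": 3,  # seq_id, position, size
    "INS": 3,  # seq_id, position, new_seq
    "MOB": 5,  # seq_id, position, repeat_name, strand, duplication_size
    "AMP": 4,  # seq_id, position, size, new_copy_number
    "CON": 4,  # seq_id, position, size, region
    "INV": 3,  # seq_id, position, size
}

_EVIDENCE_COLUMNS = {
    "RA": 5,  # seq_id, position, insert_position, ref_base, new_base
    "MC": 5,  # seq_id, start, end, start_range, end_range
    "JC": 7,  # side_1 seq/pos/strand, side_2 seq/pos/strand, overlap
    "UN": 3,  # seq_id, start, end
}

#: Attribute keys whose presence marks a record as marginal / low confidence.
DEFAULT_MARGINAL_KEYS = ("reject", "marginal")


class GDFormatError(ValueError):
    """Raised for a document-level format problem (e.g. missing header)."""


class GDRecordError(ValueError):
    """Raised for a malformed record line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass
class GDMutation:
    """One mutation record: a single, discrete change relative to the reference."""

    record_type: str
    id: str
    parent_evidence_ids: list[str]
    replicon: str
    position: int
    #: Type-specific positional fields after the position column, kept as
    #: strings in file order (e.g. ``["A"]`` for a SNP, ``["7"]`` for a DEL).
    payload: list[str] = field(default_factory=list)
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.record_type not in MUTATION_TYPES:
            raise ValueError(f"unknown mutation type {self.record_type!r}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.record_type == "DEL" and self.size < 1:
            raise ValueError("DEL size must be >= 1")
        if self.record_type == "INS" and not self.new_seq:
            raise ValueError("INS sequence must be non-empty")

    # Convenience accessors for the common payload fields.
    @property
    def new_seq(self) -> str | None:
        if self.record_type in ("SNP", "INS"):
            return self.payload[0]
        if self.record_type == "SUB":
            return self.payload[1]
        return None

    @property
    def size(self) -> int | None:
        if self.record_type in ("DEL", "SUB", "AMP", "CON", "INV"):
            return int(self.payload[0])
        if self.record_type == "SNP":
            return 1
        return None

    @property
    def end(self) -> int:
        """Last reference base touched (1-based inclusive footprint end)."""
        if self.record_type in ("DEL", "SUB", "AMP", "CON", "INV"):
            return self.position + int(self.payload[0]) - 1
        return self.position

    def is_marginal(self, marginal_keys=DEFAULT_MARGINAL_KEYS) -> bool:
        """Whether this call carries a configured low-confidence marker.

        A record is marginal if any configured key is present, or if a
        ``polymorphism_frequency`` / ``frequency`` attribute is present and
        below 1 (a non-fixed call in consensus mode).
        """
        for key in marginal_keys:
            if key in self.attributes:
                return True
        for key in ("polymorphism_frequency", "frequency"):
            raw = self.attributes.get(key)
            if raw is not None:
                try:
                    if float(raw) < 1.0:
                        return True
                except ValueError:
                    pass
        return False


@dataclass
class GDEvidence:
    """One read-level evidence record (RA, MC, JC, UN)."""

    record_type: str
    id: str
    parent_evidence_ids: list[str]
    fields: list[str]
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.record_type not in EVIDENCE_TYPES:
            raise ValueError(f"unknown evidence type {self.record_type!r}")

    @property
    def replicon(self) -> str:
        return self.fields[0]


@dataclass
class GDDocument:
    """A parsed GenomeDiff file for one strain."""

    metadata: list[tuple[str, str]]
    mutations: list[GDMutation]
    evidence: list[GDEvidence]
    unparsed: list[str] = field(default_factory=list)
    strain_id: str = ""

    def __post_init__(self) -> None:
        if not any(k == "GENOME_DIFF" for k, _ in self.metadata):
            raise GDFormatError("document lacks a GENOME_DIFF version header")
        ids = [r.id for r in self.mutations] + [r.id for r in self.evidence]
        if len(ids) != len(set(ids)):
            raise GDFormatError("record ids are not unique within document")

    @property
    def n_record_lines(self) -> int:
        return len(self.mutations) + len(self.evidence) + len(self.unparsed)


def _parse_attrs(columns: list[str]) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for col in columns:
        key, sep, value = col.partition("=")
        if not sep:
            key, value = col, ""
        attrs[key] = value
    return attrs


def parse_genomediff(text: str, strain_id: str = "") -> GDDocument:
    """Parse GD-format ``text`` into a :class:`GDDocument`.

    Every tab-separated record line yields exactly one mutation or evidence
    record; lines with unrecognized types are preserved verbatim in
    ``unparsed`` so no record is ever silently dropped.
    """
    lines = text.splitlines()
    if not lines or not lines[0].startswith("#=GENOME_DIFF"):
        raise GDFormatError("text does not begin with a #=GENOME_DIFF header")

    metadata: list[tuple[str, str]] = []
    mutations: list[GDMutation] = []
    evidence: list[GDEvidence] = []
    unparsed: list[str] = []

    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.startswith("#="):
            key, _, value = line[2:].partition("\t")
            if not value:
                key, _, value = line[2:].partition(" ")
            metadata.append((key, value.strip()))
            continue
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        rtype = cols[0]
        if rtype in MUTATION_TYPES:
            n = _MUTATION_COLUMNS[rtype]
            if len(cols) < 3 + n:
                raise GDRecordError(
                    f"{rtype} record has {len(cols)} columns, needs >= {3 + n}",
                    lineno,
                )
            try:
                position = int(cols[4])
            except ValueError as exc:
                raise GDRecordError(f"bad position {cols[4]!r}", lineno) from exc
            parents = [p for p in cols[2].split(",") if p]
            try:
                mutations.append(
                    GDMutation(
                        record_type=rtype,
                        id=cols[1],
                        parent_evidence_ids=parents,
                        replicon=cols[3],
                        position=position,
                        payload=cols[5 : 3 + n],
                        attributes=_parse_attrs(cols[3 + n :]),
                    )
                )
            except ValueError as exc:
                raise GDRecordError(str(exc), lineno) from exc
        elif rtype in EVIDENCE_TYPES:
            n = _EVIDENCE_COLUMNS[rtype]
            if len(cols) < 3 + n:
                raise GDRecordError(
                    f"{rtype} record has {len(cols)} columns, needs >= {3 + n}",
                    lineno,
                )
            parents = [p for p in cols[2].split(",") if p]
            evidence.append(
                GDEvidence(
                    record_type=rtype,
                    id=cols[1],
                    parent_evidence_ids=parents,
                    fields=cols[3 : 3 + n],
                    attributes=_parse_attrs(cols[3 + n :]),
                )
            )
        else:
            unparsed.append(line)

    return GDDocument(
        metadata=metadata,
        mutations=mutations,
        evidence=evidence,
        unparsed=unparsed,
        strain_id=strain_id,
    )


def write_genomediff(doc: GDDocument) -> str:
    """Serialize ``doc`` back to GD text; ``parse(write(doc))`` equals ``doc``."""
    out: list[str] = []
    for key, value in doc.metadata:
        out.append(f"#={key}\t{value}" if value else f"#={key}\t")
    for m in doc.mutations:
        cols = [
            m.record_type,
            m.id,
            ",".join(m.parent_evidence_ids),
            m.replicon,
            str(m.position),
            *m.payload,
        ]
        cols += [f"{k}={v}" for k, v in m.attributes.items()]
        out.append("\t".join(cols))
    for e in doc.evidence:
        cols = [e.record_type, e.id, ",".join(e.parent_evidence_ids), *e.fields]
        cols += [f"{k}={v}" for k, v in e.attributes.items()]
        out.append("\t".join(cols))
    out.extend(doc.unparsed)
    return "\n".join(out) + "\n"


def read_gd_directory(
    path: str | os.PathLike, sample_sheet: str | os.PathLike | None = None
) -> dict[str, GDDocument]:
    """Load one GD file per strain from a directory.

    Strain ids are taken from filenames (``<strain>.gd``) or, if
    ``sample_sheet`` is given, from a two-column TSV (strain_id, path) whose
    relative paths resolve against the directory.
    """
    path = Path(path)
    docs: dict[str, GDDocument] = {}
    if sample_sheet is not None:
        for line in Path(sample_sheet).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            strain_id, gd_path = line.split("\t")[:2]
            gd_file = Path(gd_path)
            if not gd_file.is_absolute():
                gd_file = path / gd_file
            docs[strain_id] = parse_genomediff(gd_file.read_text(), strain_id)
    else:
        for gd_file in sorted(path.glob("*.gd")):
            strain_id = gd_file.stem
            docs[strain_id] = parse_genomediff(gd_file.read_text(), strain_id)
    if not docs:
        raise GDFormatError(f"no GenomeDiff files found under {path}")
    return docs
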