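"""End-to-end orchestration: parse -> filter -> annotate -> catalog -> classify -> summarize.

``analyze`` is the in-memory entry point used by tests and by curated
scenarios; ``run_pipeline`` is the file-based entry point behind the CLI:
it loads the standard formats (GD directory, FASTA, GFF3, BED, manifest
and lineage YAML), runs the stages in order and writes TSV/JSON reports
into a fresh sequentially numbered run directory, stamped with the config
hash and package version so reruns never overwrite earlier outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotation import (
    DEFAULT_HOMOPOLYMER_MIN_RUN,
    DEFAULT_MOBILOME_PATTERNS,
    DEFAULT_REPLICON_LOSS_FRACTION,
    EffectAnnotation,
    FeatureIndex,
    Genome,
    annotate,
    load_gff3,
    load_repeats_bed,
)
from .catalog import (
    MutationMatrix,
    StrainManifest,
    build_matrix,
    near_miss_report,
    normalize_mutation,
)
from .filters import FilterConfig, FilterLedger, apply_exclusions, ledger_tsv
from .gd_io import GDDocument, read_gd_directory
from .lineage import Classification, LineageGraph, classifications_tsv, classify_all
from .summarize import (
    SummaryReport,
    export_genome_plot,
    export_heatmap,
    summarize_species,
)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and offending context."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage}: {detail}")
        self.stage = stage


@dataclass
class RunConfig:
    """File paths and knobs for a file-based pipeline run."""

    gd_dir: str
    fasta: str
    gff3: str
    manifest: str
    lineage: str
    out_dir: str
    bed: str | None = None
    sample_sheet: str | None = None
    species: str = ""
    marginal_keys: tuple[str, ...] = ("reject", "marginal")
    mobilome_patterns: tuple[str, ...] = DEFAULT_MOBILOME_PATTERNS
    homopolymer_min_run: int = DEFAULT_HOMOPOLYMER_MIN_RUN
    replicon_loss_fraction: float = DEFAULT_REPLICON_LOSS_FRACTION
    exclude_strains: tuple[str, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        for name in ("gd_dir", "fasta", "gff3", "manifest", "lineage"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise FileNotFoundError(f"{name} path does not exist: {path}")
        if self.bed and not Path(self.bed).exists():
            raise FileNotFoundError(f"bed path does not exist: {self.bed}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("marginal_keys", "mobilome_patterns", "exclude_strains"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in sorted(self.__dict__.items())}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class AnalysisResult:
    """Everything one species-level run produces."""

    ledgers: dict[str, FilterLedger]
    matrix: MutationMatrix
    classifications: list[Classification]
    annotations: dict[str, EffectAnnotation]
    summary: SummaryReport
    near_misses: list[dict] = field(default_factory=list)
    stage_counts: dict[str, int] = field(default_factory=dict)


def analyze(
    docs: dict[str, GDDocument],
    genome: Genome,
    features: FeatureIndex,
    manifest: StrainManifest,
    graph: LineageGraph,
    repeats=None,
    filter_config: FilterConfig | None = None,
    mobilome_patterns=DEFAULT_MOBILOME_PATTERNS,
    homopolymer_min_run: int = DEFAULT_HOMOPOLYMER_MIN_RUN,
    replicon_loss_fraction: float = DEFAULT_REPLICON_LOSS_FRACTION,
    species: str = "",
    exclude_strains: set[str] | None = None,
) -> AnalysisResult:
    """Run the full in-memory analysis for one species."""
    ledgers = {
        strain: apply_exclusions(doc, repeats, filter_config)
        for strain, doc in docs.items()
    }
    kept = {strain: ledger.kept for strain, ledger in ledgers.items()}

    matrix = build_matrix(kept, manifest, genome, features, replicon_loss_fraction)

    annotations: dict[str, EffectAnnotation] = {}
    for strain in sorted(kept):
        for m in kept[strain]:
            label = normalize_mutation(m, genome, replicon_loss_fraction).label
            if label not in annotations:
                annotations[label] = annotate(
                    m,
                    genome,
                    features,
                    repeats,
                    mobilome_patterns,
                    homopolymer_min_run,
                    replicon_loss_fraction,
                )

    classifications = classify_all(matrix, graph, manifest)
    summary = summarize_species(
        classifications,
        matrix,
        manifest,
        annotations,
        species=species,
        exclude_strains=exclude_strains,
    )
    return AnalysisResult(
        ledgers=ledgers,
        matrix=matrix,
        classifications=classifications,
        annotations=annotations,
        summary=summary,
        near_misses=near_miss_report(matrix),
        stage_counts={
            "input_records": sum(d.n_record_lines for d in docs.values()),
            "kept": sum(len(v) for v in kept.values()),
            "excluded": sum(len(ledger.excluded) for ledger in ledgers.values()),
            "columns": len(matrix.key_labels),
        },
    )


def _next_run_dir(out_dir: Path) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    n = 1
    while (out_dir / f"run-{n:04d}").exists():
        n += 1
    run_dir = out_dir / f"run-{n:04d}"
    run_dir.mkdir()
    return run_dir


def run_pipeline(cfg: RunConfig) -> Path:
    """File-based run; returns the fresh run directory it wrote."""
    try:
        cfg.validate()
    except FileNotFoundError as exc:
        raise PipelineError("validate", str(exc)) from exc

    try:
        docs = read_gd_directory(cfg.gd_dir, cfg.sample_sheet)
    except Exception as exc:
        raise PipelineError("parse", str(exc)) from exc
    try:
        genome = Genome.from_fasta(cfg.fasta)
        features = load_gff3(cfg.gff3)
        repeats = load_repeats_bed(cfg.bed) if cfg.bed else {}
        manifest = StrainManifest.from_yaml(cfg.manifest)
        graph = LineageGraph.from_yaml(cfg.lineage)
    except Exception as exc:
        raise PipelineError("load_reference", str(exc)) from exc

    try:
        result = analyze(
            docs,
            genome,
            features,
            manifest,
            graph,
            repeats,
            FilterConfig(marginal_keys=cfg.marginal_keys),
            cfg.mobilome_patterns,
            cfg.homopolymer_min_run,
            cfg.replicon_loss_fraction,
            species=cfg.species,
            exclude_strains=set(cfg.exclude_strains),
        )
    except Exception as exc:
        raise PipelineError("analyze", str(exc)) from exc

    run_dir = _next_run_dir(Path(cfg.out_dir))
    stamp = {"config_hash": cfg.digest(), "version": __version__}
    (run_dir / "run_info.json").write_text(
        json.dumps({**stamp, "stage_counts": result.stage_counts}, indent=2, sort_keys=True)
    )
    (run_dir / "filter_ledger.tsv").write_text(
        ledger_tsv([result.ledgers[s] for s in sorted(result.ledgers)])
    )
    (run_dir / "matrix.tsv").write_text(result.matrix.to_tsv())
    (run_dir / "classifications.tsv").write_text(
        classifications_tsv(result.classifications)
    )
    (run_dir / "summary.json").write_text(result.summary.to_json())
    heatmap = export_heatmap(result.matrix)
    (run_dir / "heatmap.tsv").write_text(heatmap.to_tsv())
    plot_table = export_genome_plot(result.classifications, result.annotations, genome)
    (run_dir / "genome_plot.tsv").write_text(plot_table.to_csv(sep="\t", index=False))
    near = result.near_misses
    lines = ["key_a\tkey_b\tdistance"] + [
        f"{r['key_a']}\t{r['key_b']}\t{r['distance']}" for r in near
    ]
    (run_dir / "near_misses.tsv").write_text("\n".join(lines) + "\n")
    return run_dir
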