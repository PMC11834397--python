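"""Synthetic genome / lineage / GD generation and its ground-truth contracts."""

import pytest

from halotrace._seq import revcomp, translate
from halotrace.annotation import annotate, is_mobilome
from halotrace.filters import apply_exclusions
from halotrace.synthetic_data import (
    GenomeSpec,
    LineageSpec,
    SimConfig,
    emit_dataset,
    make_genome,
    make_lineage,
    simulate_lineage_mutations,
)


def test_fixed_seed_reproduces_outputs_byte_identically(tmp_path):
    a, b = tmp_path / "a", tmp_path / "b"
    emit_dataset(SimConfig(seed=5, marginal_rate=0.5, evidence_rate=0.5), a)
    emit_dataset(SimConfig(seed=5, marginal_rate=0.5, evidence_rate=0.5), b)
    for name in ("genome.fasta", "features.gff3", "repeats.bed", "manifest.yaml",
                 "lineage.yaml", "truth.tsv"):
        assert (a / name).read_bytes() == (b / name).read_bytes(), name
    for gd in sorted((a / "gd").iterdir()):
        assert gd.read_bytes() == (b / "gd" / gd.name).read_bytes()


def test_no_is_elements_means_no_mobilome_matches():
    cfg = SimConfig(seed=1, genome=GenomeSpec(n_is_elements=0))
    syn = make_genome(cfg)
    for f in syn.features.features:
        from halotrace.gd_io import GDMutation

        m = GDMutation("SNP", "1", [], f.replicon_id, f.start + 3, ["A"])
        assert is_mobilome(m, syn.features) is False


def test_generated_cds_translate_without_internal_stops():
    syn = make_genome(SimConfig(seed=3))
    for f in syn.features.features:
        if f.kind != "CDS":
            continue
        seq = syn.genome[f.replicon_id][f.start - 1 : f.end]
        cds = seq if f.strand == "+" else revcomp(seq)
        protein = translate(cds)
        assert protein.endswith("*") and "*" not in protein[:-1], f.locus_tag
        assert cds[:3] == "ATG"


def test_zero_rate_strains_carry_exactly_inherited_intended_edits():
    cfg = SimConfig(seed=7, lambda_manipulation=0.0, lambda_transfer=0.0)
    syn = make_genome(cfg)
    docs, truth, manifest, graph = simulate_lineage_mutations(cfg, syn)
    for strain, doc in docs.items():
        n_intended = len(manifest.inherited_intended_edits(strain))
        assert len(doc.mutations) == n_intended, strain
        assert doc.evidence == []


def test_truth_and_gd_files_are_consistent():
    """Every truth mutation appears in exactly the GD files of its presence set."""
    cfg = SimConfig(seed=9, lambda_manipulation=2.0, marginal_rate=0.5,
                    homopolymer_artifact_rate=0.3, evidence_rate=0.5)
    syn = make_genome(cfg)
    docs, truth, manifest, graph = simulate_lineage_mutations(cfg, syn)
    for rec in truth.records:
        if rec.artifact_kind == "evidence":
            continue
        signature = (rec.template.record_type, rec.template.replicon,
                     rec.template.position, tuple(rec.template.payload))
        carriers = {
            strain
            for strain, doc in docs.items()
            if any(
                (m.record_type, m.replicon, m.position, tuple(m.payload)) == signature
                for m in doc.mutations
            )
        }
        assert carriers == set(rec.presence), rec.mutation_id


def test_artifact_kinds_partition_filter_outcomes():
    """marginal/repeat artifacts are exactly what filters drop; homopolymer
    artifacts survive filtering but are flagged by annotation."""
    cfg = SimConfig(seed=11, lambda_manipulation=1.0, marginal_rate=1.0,
                    repeat_artifact_rate=0.7, homopolymer_artifact_rate=0.7,
                    evidence_rate=0.5)
    syn = make_genome(cfg)
    docs, truth, manifest, graph = simulate_lineage_mutations(cfg, syn)
    repeats = syn.repeat_trees()
    sig = lambda m: (m.record_type, m.replicon, m.position, tuple(m.payload))
    removable = {"marginal", "repeat"}
    for strain, doc in docs.items():
        ledger = apply_exclusions(doc, repeats)
        excluded_mut = {sig(r) for r, why in ledger.excluded if why in
                        ("low_confidence", "repeat_region")}
        truth_artifacts = {
            sig(r.template)
            for r in truth.records
            if r.artifact_kind in removable and strain in r.presence
        }
        assert excluded_mut == truth_artifacts, strain
        kept_sigs = {sig(m) for m in ledger.kept}
        for r in truth.records:
            if r.artifact_kind == "homopolymer" and strain in r.presence:
                assert sig(r.template) in kept_sigs
                ann = annotate(r.template, syn.genome, syn.features, repeats,
                               homopolymer_min_run=cfg.genome.homopolymer_run)
                assert ann.homopolymer_artifact_candidate is True


def test_lineage_shapes_and_roles():
    for seed in range(5):
        graph, manifest = make_lineage(SimConfig(
            seed=seed, lineage=LineageSpec(n_parentals=4, n_knockouts=10)
        ))
        roles = {d["role"] for _, d in graph.graph.nodes(data=True)}
        assert roles == {"wild_type", "parental", "knockout"}
        # All knockouts sequenced; tree invariants hold via LineageGraph.
        for n, d in graph.graph.nodes(data=True):
            if d["role"] == "knockout":
                assert d["sequenced"]


def test_emitted_dataset_reloads_through_standard_readers(tmp_path):
    from halotrace.annotation import Genome, load_gff3, load_repeats_bed
    from halotrace.catalog import StrainManifest
    from halotrace.gd_io import read_gd_directory
    from halotrace.lineage import LineageGraph

    cfg = SimConfig(seed=13, lambda_manipulation=1.5)
    emit_dataset(cfg, tmp_path)
    genome = Genome.from_fasta(tmp_path / "genome.fasta")
    features = load_gff3(tmp_path / "features.gff3")
    repeats = load_repeats_bed(tmp_path / "repeats.bed")
    manifest = StrainManifest.from_yaml(tmp_path / "manifest.yaml")
    graph = LineageGraph.from_yaml(tmp_path / "lineage.yaml")
    docs = read_gd_directory(tmp_path / "gd")
    assert set(docs) == set(graph.sequenced)
    syn = make_genome(cfg)
    assert genome.replicons == syn.genome.replicons
    assert len(features.features) == len(syn.features.features)
    assert set(manifest.strains) == set(graph.graph.nodes)
    assert repeats  # at least one repeat interval loaded


def test_rate_parameterization_sets_poisson_mean():
    cfg = SimConfig(seed=1, rho=1e-9, generations_per_edge=1e4,
                    genome=GenomeSpec(replicon_lengths=(100_000,)))
    from halotrace.synthetic_data import _edge_mean

    assert _edge_mean(cfg, 100_000, "manipulation") == pytest.approx(1.0)
    assert _edge_mean(cfg, 100_000, "transfer") == pytest.approx(1.0)
    fixed = SimConfig(seed=1)
    assert _edge_mean(fixed, 100_000, "transfer") < _edge_mean(
        fixed, 100_000, "manipulation"
    )
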