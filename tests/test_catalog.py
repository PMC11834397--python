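"""Mutation identity normalization, presence matrix and intended-edit flags."""

import numpy as np
import pytest

from halotrace.annotation import FeatureIndex, Genome
from halotrace.catalog import (
    IntendedEdit,
    StrainInfo,
    StrainManifest,
    build_matrix,
    key_matches_edit,
    near_miss_report,
    normalize_mutation,
)
from halotrace.gd_io import GDMutation
from halotrace.synthetic_data import SimConfig, make_genome, simulate_lineage_mutations
from halotrace.filters import apply_exclusions


def _del(pos, size, replicon="chr"):
    return GDMutation("DEL", "1", [], replicon, pos, [str(size)])


def _ins(pos, seq, replicon="chr"):
    return GDMutation("INS", "1", [], replicon, pos, [seq])


@pytest.fixture()
def run_genome():
    #            1234567890123456789012
    return Genome({"chr": "GGTCAAAATCGGGGGATCGTAC" + "ACGT" * 10})


def test_deletion_anywhere_in_run_normalizes_to_leftmost(run_genome):
    # Run AAAA occupies positions 5-8.
    keys = {normalize_mutation(_del(p, 1), run_genome) for p in range(5, 9)}
    assert len(keys) == 1
    (key,) = keys
    assert key.position == 5 and key.kind == "DEL" and key.ref_payload == "A"


def test_insertion_in_run_normalizes_to_single_key(run_genome):
    keys = {normalize_mutation(_ins(p, "A"), run_genome) for p in range(4, 9)}
    assert len(keys) == 1


def test_exhaustive_run_shift_enumeration_matches_oracle():
    """All placements of an indel within a homopolymer map to one key."""
    rng = np.random.default_rng(13)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
    seq = seq[:100] + "T" * 9 + seq[100:]
    g = Genome({"chr": seq})
    run_start, run_end = 101, 109
    del_keys = {
        normalize_mutation(_del(p, 1), g) for p in range(run_start, run_end + 1)
    }
    ins_keys = {
        normalize_mutation(_ins(p, "T"), g) for p in range(run_start - 1, run_end + 1)
    }
    assert len(del_keys) == 1 and len(ins_keys) == 1
    # Oracle: deleting any single T of the run yields an identical sequence.
    results = {seq[: p - 1] + seq[p:] for p in range(run_start, run_end + 1)}
    assert len(results) == 1


def test_whole_replicon_deletion_becomes_replicon_loss():
    g = Genome({"chr": "ACGT" * 100, "plasmid": "ACGT" * 25})
    key = normalize_mutation(_del(1, 100, "plasmid"), g)
    assert key.kind == "REPLICON_LOSS" and key.replicon == "plasmid"
    # 99% threshold: a deletion of almost the whole replicon also collapses.
    key99 = normalize_mutation(_del(1, 99, "plasmid"), g)
    assert key99.kind == "REPLICON_LOSS"
    key_small = normalize_mutation(_del(1, 50, "plasmid"), g)
    assert key_small.kind == "DEL"


def _tiny_manifest():
    return StrainManifest(
        {
            "P": StrainInfo("P", None, "parental", False),
            "A": StrainInfo(
                "A", "P", "knockout", True,
                intended_edits=(IntendedEdit(kind="gene_deletion", locus_tag="g1"),),
            ),
            "B": StrainInfo("B", "P", "knockout", True),
            "C": StrainInfo(
                "C", "A", "knockout", True,
                intended_edits=(IntendedEdit(kind="gene_deletion", locus_tag="g2"),),
            ),
        }
    )


@pytest.fixture()
def tiny_setup():
    from halotrace.annotation import Feature

    g = Genome({"chr": "A" * 50 + "ATGGCTGCTTAA" + "C" * 38 + "ATGGGTGGATAA" + "T" * 48})
    f1 = Feature("chr", 51, 62, "+", "CDS", "g1")
    f2 = Feature("chr", 101, 112, "+", "CDS", "g2")
    return g, FeatureIndex([f1, f2])


def test_matrix_shared_and_private_columns(tiny_setup):
    g, idx = tiny_setup
    manifest = _tiny_manifest()
    shared = GDMutation("SNP", "1", [], "chr", 10, ["C"])
    private = GDMutation("SNP", "2", [], "chr", 20, ["G"])
    kept = {
        "A": [shared],
        "B": [shared, private],
        "C": [],
    }
    matrix = build_matrix(kept, manifest, g, idx)
    shared_label = normalize_mutation(shared, g).label
    assert matrix.presence(shared_label) == {"A", "B"}
    private_label = normalize_mutation(private, g).label
    assert matrix.presence(private_label) == {"B"}
    assert len(matrix.key_labels) == 2


def test_intended_inheritance_is_transitive(tiny_setup):
    """A knockout carries its own and every ancestor's intended edits."""
    g, idx = tiny_setup
    manifest = _tiny_manifest()
    del_g1 = GDMutation("DEL", "1", [], "chr", 41, ["32"])  # covers g1
    del_g2 = GDMutation("DEL", "2", [], "chr", 91, ["32"])  # covers g2
    kept = {"A": [del_g1], "B": [], "C": [del_g1, del_g2]}
    matrix = build_matrix(kept, manifest, g, idx)
    k1 = normalize_mutation(del_g1, g).label
    k2 = normalize_mutation(del_g2, g).label
    assert matrix.states.loc["A", k1] == 2  # own edit
    assert matrix.states.loc["C", k1] == 2  # inherited from parent A
    assert matrix.states.loc["C", k2] == 2
    assert matrix.is_intended(k1) and matrix.is_intended(k2)


def test_duplicate_records_add_no_columns(tiny_setup):
    g, idx = tiny_setup
    manifest = _tiny_manifest()
    snp = GDMutation("SNP", "1", [], "chr", 10, ["C"])
    dup = GDMutation("SNP", "2", [], "chr", 10, ["C"])
    matrix = build_matrix({"A": [snp, dup], "B": [], "C": []}, manifest, g, idx)
    assert len(matrix.key_labels) == 1


def test_strain_missing_from_manifest_errors(tiny_setup):
    g, idx = tiny_setup
    with pytest.raises(KeyError):
        build_matrix({"ZZZ": []}, _tiny_manifest(), g, idx)


def test_key_matches_edit_kinds(tiny_setup):
    g, idx = tiny_setup
    covers_g1 = normalize_mutation(GDMutation("DEL", "1", [], "chr", 41, ["32"]), g)
    partial_g1 = normalize_mutation(GDMutation("DEL", "2", [], "chr", 55, ["4"]), g)
    assert key_matches_edit(covers_g1, IntendedEdit("gene_deletion", locus_tag="g1"), idx)
    assert not key_matches_edit(partial_g1, IntendedEdit("gene_deletion", locus_tag="g1"), idx)
    loss = normalize_mutation(GDMutation("DEL", "3", [], "chr", 1, ["160"]), g)
    assert key_matches_edit(loss, IntendedEdit("replicon_loss", replicon="chr"), idx)


def test_matrix_equals_simulator_truth_table():
    cfg = SimConfig(seed=8, lambda_manipulation=2.5)
    syn = make_genome(cfg)
    docs, truth, manifest, graph = simulate_lineage_mutations(cfg, syn)
    kept = {s: apply_exclusions(d).kept for s, d in docs.items()}
    matrix = build_matrix(kept, manifest, syn.genome, syn.features)
    for rec in truth.observable():
        label = normalize_mutation(rec.template, syn.genome).label
        assert matrix.presence(label) == set(rec.presence), rec.mutation_id


def test_manifest_yaml_round_trip(tmp_path):
    manifest = _tiny_manifest()
    path = tmp_path / "manifest.yaml"
    path.write_text(manifest.to_yaml())
    again = StrainManifest.from_yaml(path)
    assert again == manifest
    assert again.inherited_intended_edits("C") == [
        IntendedEdit(kind="gene_deletion", locus_tag="g2"),
        IntendedEdit(kind="gene_deletion", locus_tag="g1"),
    ]


def test_near_miss_report_surfaces_close_keys(tiny_setup):
    g, idx = tiny_setup
    manifest = _tiny_manifest()
    a = GDMutation("SNP", "1", [], "chr", 30, ["C"])
    b = GDMutation("SNP", "2", [], "chr", 36, ["G"])
    far = GDMutation("SNP", "3", [], "chr", 90, ["G"])
    matrix = build_matrix({"A": [a], "B": [b], "C": [far]}, manifest, g, idx)
    report = near_miss_report(matrix, max_distance=10)
    assert len(report) == 1
    assert report[0]["distance"] == 6
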