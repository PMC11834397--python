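import numpy as np
import pytest

from halotrace.pipeline import analyze
from halotrace.study import build_hbt_panel, build_hfx_panel
from halotrace.synthetic_data import RepliconBuilder

from halotrace.annotation import FeatureIndex, Genome


@pytest.fixture(scope="session")
def hbt_panel():
    return build_hbt_panel(seed=1)


@pytest.fixture(scope="session")
def hfx_panel():
    return build_hfx_panel(seed=1)


def _run(panel):
    return analyze(
        panel.docs(),
        panel.genome,
        panel.features,
        panel.manifest,
        panel.graph,
        species=panel.species,
        exclude_strains=set(panel.exclude_strains),
    )


@pytest.fixture(scope="session")
def hbt_result(hbt_panel):
    return _run(hbt_panel)


@pytest.fixture(scope="session")
def hfx_result(hfx_panel):
    return _run(hfx_panel)


@pytest.fixture()
def toy_genome():
    """Small two-replicon genome with designed genes for annotation tests.

    chromosome: geneA (+, with planted codons), geneB (-), an IS element,
    a pseudogene, a poly-C tract in the intergenic space; plasmid: one gene.
    """
    rng = np.random.default_rng(42)
    b = RepliconBuilder("chromosome", rng)
    b.add_spacer(60)
    gene_a = b.add_cds(
        "geneA",
        "widget synthase",
        n_codons=60,
        strand="+",
        codon_overrides={5: "CTG", 10: "GGC", 20: "TGG", 30: "AGC"},
    )
    b.add_spacer(80)
    gene_b = b.add_cds(
        "geneB",
        "widget reductase",
        n_codons=60,
        strand="-",
        codon_overrides={5: "CTG", 10: "GGC"},
    )
    b.add_spacer(40)
    tract_start, _ = b.add_homopolymer("C", 7)
    is_gene = b.add_cds("isg", "IS5 family transposase", n_codons=50, strand="+")
    b.add_spacer(50)
    pseudo = b.add_cds("pseu", "degenerate fragment", n_codons=40, kind="pseudogene")
    b.add_spacer(60)
    chrom = b.sequence

    b2 = RepliconBuilder("plasmid", rng)
    b2.add_spacer(30)
    gene_p = b2.add_cds("geneP", "plasmid protein", n_codons=40, strand="+")
    b2.add_spacer(30)

    genome = Genome({"chromosome": chrom, "plasmid": b2.sequence})
    index = FeatureIndex([gene_a, gene_b, is_gene, pseudo, gene_p])
    return {
        "genome": genome,
        "features": index,
        "geneA": gene_a,
        "geneB": gene_b,
        "is_gene": is_gene,
        "pseudo": pseudo,
        "geneP": gene_p,
        "tract_start": tract_start,
    }
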