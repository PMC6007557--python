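import pytest

from genorigin.classify import classify_genome
from genorigin.islands import detect_islands
from genorigin.model import Gene, TaxonomyMap, make_hit
from genorigin.simulate import SimulationConfig, generate

FOCAL = "Spiroplasma clarkii"

TAXA = {
    FOCAL: "Apis",
    "Apis sp. A": "Apis",
    "Apis sp. B": "Apis",
    "Mycoides sp. A": "Mycoides-Entomoplasmataceae",
    "Mycoides sp. B": "Mycoides-Entomoplasmataceae",
    "Citri sp. A": "Citri-Chrysopicola-Mirum",
    "Acholeplasma sp. A": "other-Mollicutes",
    "Bacillus sp. A": "non-Mollicutes",
}


@pytest.fixture
def taxonomy():
    return TaxonomyMap(entries=dict(TAXA), focal_clade="Apis", focal_taxon=FOCAL)


@pytest.fixture
def hit_factory():
    """Builds hits with sensible defaults; length_aa fixed at 100."""

    def build(
        query="g1",
        subject="s1",
        taxon="Apis sp. A",
        similarity=80.0,
        q_start=1,
        q_end=95,
        score=200.0,
        length_aa=100,
    ):
        return make_hit(query, subject, taxon, similarity, q_start, q_end, score, length_aa)

    return build


@pytest.fixture
def gene_factory():
    def build(gene_id="g1", start=1, end=300, strand="+", length_aa=100, cog=None):
        return Gene(
            gene_id=gene_id, start=start, end=end, strand=strand,
            length_aa=length_aa, cog=cog,
        )

    return build


@pytest.fixture(scope="session")
def flagship_bundle():
    """Noise-free simulation at the flagship study conditions (n=1,346)."""
    return generate(SimulationConfig(seed=20260401))


@pytest.fixture(scope="session")
def flagship_calls(flagship_bundle):
    b = flagship_bundle
    return classify_genome(b.genes, b.hits, b.taxonomy, absent_means_no_hits=True)


@pytest.fixture(scope="session")
def flagship_islands(flagship_calls, flagship_bundle):
    return detect_islands(flagship_calls, flagship_bundle.genes)


@pytest.fixture(scope="session")
def small_bundle():
    """A small, fast fixture for IO round trips and CLI tests."""
    cfg = SimulationConfig(
        seed=7,
        n_genes=160,
        chrom_len_bp=200_000,
        class_fractions=(0.50, 0.25, 0.10, 0.15),
        n_islands=2,
        island_sizes=(6, 5),
        n_tree_candidates=3,
    )
    return generate(cfg)
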