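import pytest

from gselexmine.synthetic_data import build_library, generate_genome, plant_motifs


@pytest.fixture(scope="session")
def small_genome():
    """20-gene two-contig genome used across modules."""
    return generate_genome(n_genes=20, contig_length=25_000, seed=11)


@pytest.fixture(scope="session")
def planted_genome(small_genome):
    """Genome with known sites written into the first three promoters."""
    plan = {
        "g01": [("GGCTAA", 500, "+"), ("GGCTGA", 200, "-")],
        "g02": [("GGCTAA", 990, "+")],
        "g03": [("CGGNTAAW", 50, "+"), ("TTAGSCTAA", 700, "-")],
    }
    genome, truth = plant_motifs(small_genome, plan, seed=3)
    return genome, truth


@pytest.fixture(scope="session")
def small_library(small_genome):
    return build_library(small_genome, n_fragments=2000, seed=5)
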