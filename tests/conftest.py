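import pytest

from crpevol.collinearity import HomologPair
from crpevol.genome_io import write_gff, write_pairs_table
from crpevol.synthetic import simulate_genome, write_truth

GENOME_PARAMS = dict(
    n_chromosomes=4,
    genes_per_chromosome=100,
    n_clusters=5,
    cluster_gap_bp=2000,
    n_tandem_arrays=4,
    n_collinear_segments=3,
    segment_length_anchors=6,
    seed=42,
)


@pytest.fixture(scope="session")
def synthetic_genome():
    """One standard planted genome: (annotation, pair rows, truth)."""
    return simulate_genome(**GENOME_PARAMS)


@pytest.fixture(scope="session")
def homolog_pairs(synthetic_genome):
    _, pair_rows, _ = synthetic_genome
    return [HomologPair(a, b, sc, ev) for a, b, sc, ev in pair_rows]


@pytest.fixture()
def genome_files(tmp_path, synthetic_genome):
    """The same genome written to disk in its external formats."""
    genes, pair_rows, truth = synthetic_genome
    write_gff(genes, tmp_path / "annotation.gff3")
    write_pairs_table(pair_rows, tmp_path / "pairs.tsv")
    write_truth(truth, tmp_path)
    return tmp_path
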