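import numpy as np
import pytest

from rbsprox import (SimConfig, build_occurrence_index, compile_motif,
                     exact_background, make_genome, simulate_dataset)

# printed oligonucleotide probes spanning the three integration-hotspot
# Rep-binding-site regions (complementary strands) and the Rep-binding-
# deficient GAGG-substituted control
AAVS1_OLIGO = "GCCCGCCCGCCCAGCGAGCGAGCGAGCGCCGAGCCCCAACCGCCGCCA"
AAVS2_OLIGO = "ACAAAGCGGTGAGGGGAGAGTGAGTGAGCGAGCGTGGGGTCCAGCT"
AAVS3_OLIGO = "GTGAGGAGTGAGTGAGTGAGCGAGCGCACATTCATTCCCCTTGGGAAGC"
AAVS2_MUT_OLIGO = "ACAAAGCGGTGAGGGGAGAGGGAGGGAGCGAGGGTGGGGTCCAGCT"


def random_sequence(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture(scope="session")
def small_genome():
    """A 2 x 200 kb synthetic genome with planted GAGCGAGC motifs."""
    cfg = SimConfig(seed=11, contig_lengths=(200_000, 200_000),
                    repeat_block_len=0)
    genome, planted = make_genome(cfg)
    return cfg, genome, planted


@pytest.fixture(scope="session")
def small_index(small_genome):
    cfg, genome, _ = small_genome
    return build_occurrence_index(genome, compile_motif(cfg.motif))


@pytest.fixture(scope="session")
def clean_dataset():
    """Noiseless synthetic dataset: no decoys, no repeat block."""
    cfg = SimConfig(seed=5, contig_lengths=(300_000, 300_000), n_sites=30,
                    n_pure_viral=0, n_short_human=0, n_long_gap=0,
                    n_duplicate=0, n_repeat=0, repeat_block_len=0)
    return cfg, simulate_dataset(cfg)


@pytest.fixture(scope="session")
def decoy_dataset():
    """Full decoy suite on a small genome."""
    cfg = SimConfig(seed=7, contig_lengths=(250_000, 250_000), n_sites=25,
                    n_pure_viral=4, n_short_human=4, n_long_gap=4,
                    n_duplicate=4, n_repeat=4)
    return cfg, simulate_dataset(cfg)
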