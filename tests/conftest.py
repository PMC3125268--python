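import pytest

from ntarseq import SimulationConfig

# conditions for small-genome oracle tests: one 100 kb chromosome, five genes,
# one planted nTAR per class, a 3 kb neighbourhood window scaled to the genome
MINI_KWARGS = dict(
    n_chromosomes=1,
    chrom_length=100_000,
    n_genes=5,
    intergenic_gap=(7000, 9000),
    exons_per_gene=(3, 5),
    exon_length_logmean=5.0,
    exon_length_clip=(80, 300),
    intron_length_logmean=6.2,
    intron_length_clip=(160, 800),
    n_long_genes=0,
    isoforms_per_gene=(1, 2),
    ntars_per_class=1,
    ntar_length_range=(60, 150),
    neighbourhood_window=3000,
    depth_multiplier=30.0,
)


def mini_config(seed: int, **overrides) -> SimulationConfig:
    kwargs = {**MINI_KWARGS, **overrides}
    return SimulationConfig(seed=seed, **kwargs)


@pytest.fixture
def mini_genome():
    from ntarseq import simulate_genome

    return simulate_genome(mini_config(7))


@pytest.fixture(scope="session")
def default_genome():
    from ntarseq import simulate_genome

    return simulate_genome(SimulationConfig(seed=11))
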