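import pytest

from notocraft import synthetic_data as sd


@pytest.fixture(scope="session")
def small_genome():
    """A 4-chromosome synthetic genome with annotation (session-wide)."""
    spec = sd.GenomeSpec(
        n_chromosomes=4,
        chrom_length_range=(400_000, 600_000),
        gene_count_per_chrom=60,
        seed=11,
    )
    return sd.generate_genome(spec)


@pytest.fixture(scope="session")
def scrub_scenario():
    """Reads with planted chimeras plus idealized overlaps (~25x depth)."""
    spec = sd.GenomeSpec(
        n_chromosomes=2,
        chrom_length_range=(500_000, 500_000),
        gene_count_per_chrom=10,
        repeat_count_per_chrom=10,
        seed=21,
    )
    genome, _ = sd.generate_genome(spec)
    rspec = sd.ReadSimSpec(
        n_reads=2_000, median_len=12_000, sigma=0.25,
        chimera_rate=0.05, min_len=3_000, seed=22,
    )
    reads, truth = sd.simulate_long_reads(genome, rspec)
    overlaps = sd.make_overlaps(reads, truth)
    return reads, truth, overlaps
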