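import logging

import pytest

import niptcnv as nc

logging.getLogger("niptcnv").setLevel(logging.ERROR)

#: compact genome for unit tests; same chromosome roster as the default
#: genome but shorter, so one simulation costs a few milliseconds
SMALL_LENGTHS = {"chr13": 30_000_000, "chr18": 22_000_000,
                 "chr21": 12_000_000, "chrX": 18_000_000}
SMALL_READS = 1_500_000


@pytest.fixture(scope="session")
def genome_small():
    return nc.make_genome_fixture(SMALL_LENGTHS, seed=2)


@pytest.fixture(scope="session")
def panel_small(genome_small):
    samples = nc.simulate_reference_panel(genome_small, n_samples=100,
                                          total_reads=SMALL_READS, seed=7)
    return nc.build_reference_panel(samples, genome_small)


@pytest.fixture(scope="session")
def genome_big():
    """Full-size synthetic genome (chr13/18/21-like + chrX-like)."""
    return nc.default_genome(seed=1)


@pytest.fixture(scope="session")
def panel_big(genome_big):
    samples = nc.simulate_reference_panel(genome_big, n_samples=100, seed=7)
    return nc.build_reference_panel(samples, genome_big)


def small_params(**kw):
    kw.setdefault("total_reads", SMALL_READS)
    return nc.SimulationParams(**kw)
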