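import numpy as np
import pytest

from zwscan.simdata import (SimConfig, simulate_dna_profiles,
                            simulate_expression, simulate_genome)


def small_config(**kw) -> SimConfig:
    """A 3-chromosome toy genome with the SD region on half of chr3."""
    d = dict(n_chromosomes=3, scaffolds_per_chromosome=5, scaffold_length=2000,
             sd_chromosome="chr3", sd_interval=(2000, 8000),
             n_females=2, n_males=2, seed=7)
    d.update(kw)
    return SimConfig(**d)


def rna_config(seed=0, **kw) -> SimConfig:
    """Gene-dense scaled genome for expression/ASE analyses.

    The SD region spans one of three chromosomes (60 of 180 genes), with
    three RNA genotypes per sex.
    """
    d = dict(n_chromosomes=3, scaffolds_per_chromosome=5, scaffold_length=4800,
             sd_chromosome="chr3", sd_interval=(0, 24000),
             genes_per_scaffold=12, n_females=3, n_males=3,
             frac_masculinized=1.0, seed=seed)
    d.update(kw)
    return SimConfig(**d)


@pytest.fixture(scope="session")
def small_truth():
    return simulate_genome(small_config())


@pytest.fixture(scope="session")
def small_profiles(small_truth):
    return simulate_dna_profiles(small_truth)


@pytest.fixture(scope="session")
def small_expression(small_truth):
    return simulate_expression(small_truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
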