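import warnings

import numpy as np
import pytest

from ibdthread.driver import ThreadConfig, run_thread
from ibdthread.pedigree import assign_generations
from ibdthread.simulate import (SimConfig, example_pedigree, gene_drop,
                                simulate_pedigree, true_ibd_segments)

warnings.filterwarnings("ignore", message=".*no parents, spouse or children.*")


@pytest.fixture(scope="session")
def looped_example():
    """The worked-example looped pedigree and its five-member cohort."""
    return example_pedigree()


@pytest.fixture(scope="session")
def small_sim():
    """A quick simulation for unit tests (6 generations, short chromosome)."""
    cfg = SimConfig(generations=6, couples_per_generation=8, n_snps=1200,
                    chrom_cm=60.0, seed=1)
    ped = simulate_pedigree(cfg)
    truth = gene_drop(ped, cfg)
    segments = true_ibd_segments(truth, ped)
    return cfg, ped, truth, segments


@pytest.fixture(scope="session")
def default_sim():
    """The default desk-scale study conditions: 8 generations, ~300
    individuals, 5000 SNPs over 100 cM, bottom three generations genotyped,
    true IBD input with a 3 cM floor."""
    cfg = SimConfig(seed=1)
    ped = simulate_pedigree(cfg)
    truth = gene_drop(ped, cfg)
    segments = true_ibd_segments(truth, ped)
    return cfg, ped, truth, segments


@pytest.fixture(scope="session")
def default_run(default_sim):
    """One full reconstruction under the default conditions."""
    cfg, ped, truth, segments = default_sim
    panel = truth.to_panel(ped)
    result = run_thread(ped, panel, segments, ThreadConfig())
    return ped, truth, segments, panel, result


@pytest.fixture(scope="session")
def default_generations(default_sim):
    _, ped, _, _ = default_sim
    return assign_generations(ped)


def truth_pair(truth, ind):
    return truth.haplotypes[(ind, 0)], truth.haplotypes[(ind, 1)]
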