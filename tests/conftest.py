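import numpy as np
import pytest

from qtlblup.pipeline import ExperimentConfig, run_experiment
from qtlblup.popsim import GenomeMap


@pytest.fixture(scope="session")
def mini_experiment():
    """Ten replicates of the scaled-down study, shared across ordering tests."""
    cfg = ExperimentConfig.mini_ci(seed=7, n_replicates=10, thresholds=(0.0, 0.8, 1.0))
    return cfg, run_experiment(cfg)


@pytest.fixture(scope="session")
def tiny_genome():
    """Two chromosomes, 40 loci: big enough to exercise recombination."""
    return GenomeMap.random(
        n_chromosomes=2, chrom_length_cM=100.0,
        n_qtl_per_chromosome=5, n_snp_per_chromosome=15, seed=11,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
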