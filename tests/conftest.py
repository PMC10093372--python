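import numpy as np
import pytest

import gsel


@pytest.fixture(scope="session")
def herd400():
    """Default desk-scale herd: ~400 animals, 1,000 SNPs, h2 = 0.30."""
    return gsel.simulate_herd(gsel.default_config(seed=11, n_snps=1000))


@pytest.fixture(scope="session")
def family_herd():
    """Ten distinct full-sib families — the structure that separates
    dissimilarity-clustered folds from random folds."""
    return gsel.simulate_herd(
        gsel.family_herd_config(
            n_families=10, offspring_per_family=12, seed=2, n_snps=600
        )
    )


@pytest.fixture(scope="session")
def tiny_herd():
    """Small, fast herd (80 animals) for I/O and QC round-trips."""
    cfg = gsel.default_config(
        seed=5,
        n_founders=20,
        n_generations=2,
        matings_per_generation=10,
        offspring_per_mating=3,
        n_chromosomes=2,
        chrom_length_mb=20.0,
        n_snps=120,
        n_qtl=20,
        missing_rate=0.02,
    )
    return gsel.simulate_herd(cfg)


def pearson(x, y):
    return float(np.corrcoef(np.asarray(x), np.asarray(y))[0, 1])
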