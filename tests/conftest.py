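import numpy as np
import pytest

import qtlwin as qw


@pytest.fixture(scope="session")
def small_study():
    """~470 individuals, 4 generations (last unphenotyped), 500 SNPs, 10 QTL."""
    cfg = qw.StudyConfig(
        pedigree=qw.PedigreeConfig(n_generations=4, n_dams=40, offspring_per_dam=5),
        n_snps=500, qtl_counts=qw.QTLCounts(10, 0, 0))
    return qw.simulate_study(cfg, seed=42)


@pytest.fixture(scope="session")
def full_feature_study():
    """Small study with epistatic pairs and imprinted loci, phase retained."""
    cfg = qw.StudyConfig(
        pedigree=qw.PedigreeConfig(n_founders=20, n_founder_males=5,
                                   n_generations=3, n_dams=30,
                                   offspring_per_dam=6),
        n_snps=200, qtl_counts=qw.QTLCounts(8, 2, 3))
    return qw.simulate_study(cfg, seed=7)


@pytest.fixture
def toy_pedigree():
    """10 individuals over 3 generations, mixed founders/non-founders."""
    return qw.popsim.Pedigree(
        sire=np.array([-1, -1, -1, -1, 0, 0, 0, 4, 4, 4]),
        dam=np.array([-1, -1, -1, -1, 1, 2, 3, 5, 6, 6]),
        sex=np.array([0, 1, 1, 1, 0, 1, 1, 0, 1, 1]),
        generation=np.array([0, 0, 0, 0, 1, 1, 1, 2, 2, 2]))
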