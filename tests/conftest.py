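"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from hoofgen.genomics import GenotypeData
from hoofgen.simulate import preset, simulate


@pytest.fixture(scope="session")
def wc_sim():
    """Small within-country dataset (continuous records) for model tests."""
    cfg = preset(
        "paper-wc-us", seed=11, score_thresholds=None,
        animals_per_generation_per_country=250, n_founders=120,
        cg_count_per_country=10,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def mc_sim():
    """Small two-country dataset with shared sires."""
    cfg = preset(
        "paper-mc", seed=7, score_thresholds=None,
        animals_per_generation_per_country=150, n_founders=140,
        cg_count_per_country=8,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def genomic_sim():
    """Genotyped dataset (genomic TBV mode) for ssGBLUP/GWAS tests."""
    cfg = preset(
        "paper-mc-genomic", seed=13, score_thresholds=None,
        animals_per_generation_per_country=120, n_founders=120,
        n_snps=600, cg_count_per_country=6,
    )
    return simulate(cfg)


@pytest.fixture
def random_genotypes():
    rng = np.random.default_rng(42)
    m, n = 80, 60
    snp_map = pd.DataFrame(
        {"snp": [f"s{j}" for j in range(m)], "chrom": 1,
         "bp": np.sort(rng.choice(10_000_000, m, replace=False))}
    )
    p = rng.uniform(0.1, 0.9, m)
    dos = rng.binomial(2, p, size=(n, m)).astype(float)
    ids = np.array([f"a{i}" for i in range(n)], dtype=object)
    return GenotypeData(dos, snp_map, ids)
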