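import numpy as np
import pandas as pd
import pytest

from ghostflow import GenotypeMatrix, ScenarioParams, SampleConfig


@pytest.fixture
def toy_matrix():
    """Two groups (A: 4 diploids, B: 4 diploids), 6 hand-built sites."""
    geno = np.array([
        # sites:   s1 s2 s3 s4 s5 s6
        [0, 1, 2, 0, 1, 0],   # A1
        [0, 1, 2, 0, 1, 0],   # A2
        [1, 1, 2, 0, 0, 0],   # A3
        [1, 1, 2, 0, 0, -1],  # A4
        [2, 1, 0, 0, 2, 1],   # B1
        [2, 1, 0, 0, 2, 1],   # B2
        [2, 1, 0, 0, 1, 1],   # B3
        [1, 1, 0, 0, 2, 1],   # B4
    ], dtype=np.int8)
    sites = pd.DataFrame({
        "chrom": ["chr1"] * 4 + ["chr2"] * 2,
        "pos": [100, 200, 300, 400, 150, 250],
        "ref": list("ACGTAC"), "alt": list("TGCAGT"),
    })
    indiv = pd.DataFrame({
        "id": [f"A{i}" for i in range(1, 5)] + [f"B{i}" for i in range(1, 5)],
        "population": ["popA"] * 4 + ["popB"] * 4,
        "group": ["A"] * 4 + ["B"] * 4,
    })
    return GenotypeMatrix(genotypes=geno, sites=sites, individuals=indiv)


@pytest.fixture
def ghgea_median_params():
    """GhGeA at a strongly diverged, bottlenecked parameter point."""
    return ScenarioParams(
        scenario="GhGeA", N_A=2228, N_B=2505, N_aA=10318, N_aB=11436,
        N_anc=2.62, N_ghost=10318, m_A=1.03e-3, m_B=1.12e-3,
        m_G=4.6e-4, m_AG=2.4e-4, T_m=4252, T_div=301759, T_divG=411780,
        T_G=8249)


@pytest.fixture
def small_config():
    return SampleConfig(n_snps=200)
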