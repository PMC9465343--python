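import numpy as np
import pytest

from pgskit import ldref, simdata, sumstats as ss


@pytest.fixture(scope="session")
def small_panel():
    """2,000 individuals x 500 variants with blocky, decaying LD."""
    return simdata.simulate_genotypes(
        2_000, 500, ld_decay=1.5, n_founder_haplotypes=8, seed=101,
        genetic_map="hotspot")


@pytest.fixture(scope="session")
def small_pheno(small_panel):
    return simdata.simulate_phenotype(small_panel, h2=0.3, n_causal=50,
                                      seed=102)


@pytest.fixture(scope="session")
def small_gwas(small_panel, small_pheno):
    return simdata.run_gwas_linear(small_panel, small_pheno.y, 1.0, seed=103)


@pytest.fixture(scope="session")
def small_ld(small_panel):
    return ldref.build_ld(small_panel, window_cm=3.0)


@pytest.fixture(scope="session")
def small_scaled(small_gwas):
    return ss.scaled_effects(small_gwas)


@pytest.fixture()
def toy_sumstats():
    """Five hand-sized variants with complete metadata."""
    import pandas as pd

    df = pd.DataFrame({
        "chr": ["1", "1", "2", "2", "6"],
        "pos": [100, 200, 100, 400, 28_000_000],
        "a0": ["A", "C", "G", "A", "C"],
        "a1": ["C", "T", "A", "T", "G"],
        "beta": [0.10, -0.05, 0.20, 0.00, 0.08],
        "beta_se": [0.020, 0.015, 0.050, 0.010, 0.030],
        "freq": [0.30, 0.45, 0.10, 0.25, 0.40],
        "info": [1.00, 0.90, 0.64, 0.80, 0.95],
        "n": [10_000.0, 9_000.0, 8_000.0, 10_000.0, 7_000.0],
    })
    return ss.SumStats(df, n_total=10_000, var_y=1.0)
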