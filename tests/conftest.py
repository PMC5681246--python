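import numpy as np
import pandas as pd
import pytest

from mpspred.simulate import (
    GenotypePanel,
    SimulationConfig,
    simulate_genotypes,
    simulate_ld_structure,
)


@pytest.fixture(scope="session")
def small_panel() -> GenotypePanel:
    """1000 individuals x 120 SNPs in 4 LD blocks with rho = 0.5."""
    ld = simulate_ld_structure(120, 4, 0.5)
    return simulate_genotypes(1000, ld, maf_range=(0.1, 0.5), seed=11)


@pytest.fixture(scope="session")
def independent_panel() -> GenotypePanel:
    """2000 individuals x 100 independent SNPs."""
    ld = simulate_ld_structure(100, 100, 0.0)
    return simulate_genotypes(2000, ld, maf_range=(0.1, 0.5), seed=5)


def toy_panel(alleles, mafs=None, n=200, seed=0):
    """Hand-built panel with specified allele pairs (list of (a1, a2))."""
    m = len(alleles)
    rng = np.random.default_rng(seed)
    mafs = np.full(m, 0.3) if mafs is None else np.asarray(mafs, float)
    dosages = rng.binomial(2, mafs, size=(n, m)).astype(np.int8)
    variants = pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1}" for i in range(m)],
            "chr": 1,
            "bp": np.arange(1, m + 1) * 1000,
            "a1": [a for a, _ in alleles],
            "a2": [b for _, b in alleles],
            "maf": mafs,
        }
    )
    return GenotypePanel(dosages, variants, [f"id{i + 1}" for i in range(n)])
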