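import numpy as np
import pandas as pd
import pytest

from xqtl.simdata import simulate_ri_genotypes, simulate_trait, uniform_marker_map
from xqtl.types import MarkerMap, QTLSpec, StrainGenotypes


@pytest.fixture(scope="session")
def small_map() -> MarkerMap:
    """Two chromosomes, 60 cM each, one marker per 2 cM (pos_Mb = pos_cM)."""
    return uniform_marker_map(n_chrom=2, chrom_length_cM=60, spacing_cM=2, Mb_per_cM=1.0)


@pytest.fixture(scope="session")
def panel_80(small_map) -> StrainGenotypes:
    return simulate_ri_genotypes(80, small_map, seed=11)


@pytest.fixture(scope="session")
def planted_trait(panel_80) -> tuple[pd.Series, str]:
    causal = "m1_015"
    y = simulate_trait(panel_80, QTLSpec(causal, a=1.0, h2=0.5), seed=23)
    return y, causal


def two_group_lrs_oracle(y: np.ndarray, g: np.ndarray) -> float:
    """Brute-force LRS: 2 * log-likelihood ratio of two explicit Gaussian fits.

    Null: one Gaussian (ML mean/variance) for all strains.  Alternative: a
    separate mean per allele group with a shared ML variance.  Both use the
    maximized Gaussian log-likelihood directly, independent of the scan's
    correlation-identity shortcut.
    """
    n = len(y)

    def loglik(resid: np.ndarray) -> float:
        s2 = float(np.mean(resid**2))
        return -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)

    ll0 = loglik(y - y.mean())
    resid = y.copy()
    for allele in np.unique(g):
        mask = g == allele
        resid[mask] = y[mask] - y[mask].mean()
    ll1 = loglik(resid)
    return 2.0 * (ll1 - ll0)
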