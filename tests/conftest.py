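import warnings

import numpy as np
import pandas as pd
import pytest

from ldscape import GenotypeMatrix, SimConfig, apply_qc, simulate_population


def make_genotypes(dosage, positions=None, chrom=1, populations="pop"):
    """Small GenotypeMatrix from a dense dosage array (-1 = missing)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if positions is None:
        positions = (np.arange(m) + 1) * 10_000
    chroms = [chrom] * m if np.isscalar(chrom) else list(chrom)
    samples = pd.DataFrame(
        {"iid": [f"s{i}" for i in range(n)], "population": populations}
    )
    variants = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": list(positions),
            "vid": [f"v{j}" for j in range(m)],
            "allele1": "A",
            "allele2": "B",
        }
    )
    return GenotypeMatrix(samples, variants, dosage)


@pytest.fixture(scope="session")
def wf_cohort():
    """A moderate Wright-Fisher cohort shared across tests (MAF-filtered)."""
    G, truth = simulate_population(
        SimConfig(N=100, n_chrom=12, seed=12345, population="wf")
    )
    Gq, _ = apply_qc(G, call_rate_min=0.0, maf_min=0.05, hwe_p_min=0.0)
    return Gq, truth


@pytest.fixture(autouse=True)
def _silence_colocated_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("default")
        yield
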