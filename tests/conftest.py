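import numpy as np
import pandas as pd
import pytest

from iterprs import CohortSpec, GenotypeDataset, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Complete 300 x 600 cohort with 15 causal SNPs at h2 = 0.3."""
    spec = CohortSpec(n_samples=300, n_snps=600, n_causal=15, heritability=0.3, seed=42)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def assoc_cohort():
    """Larger cohort for parameter-recovery checks (n = 2000)."""
    spec = CohortSpec(n_samples=2000, n_snps=800, n_causal=40, heritability=0.3, seed=9)
    return simulate_cohort(spec)


def tiny_dataset(dosages, alleles=None, chrom=None, pos=None, pheno=None, sample_prefix="S"):
    """Hand-built GenotypeDataset from a dosage matrix (rows = samples)."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    if alleles is None:
        alleles = [("A", "G")] * m
    variants = pd.DataFrame(
        {
            "id": [f"v{j}" for j in range(m)],
            "chrom": ["1"] * m if chrom is None else list(map(str, chrom)),
            "pos": list(range(1000, 1000 + m)) if pos is None else pos,
            "allele1": [a for a, _ in alleles],
            "allele2": [b for _, b in alleles],
        }
    )
    ids = [f"{sample_prefix}{i}" for i in range(n)]
    table = None
    if pheno is not None:
        table = pd.DataFrame({"phenotype": np.asarray(pheno, float)}, index=ids)
    return GenotypeDataset(ids, variants, d, phenotable=table)


@pytest.fixture
def make_dataset():
    return tiny_dataset
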