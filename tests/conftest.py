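import numpy as np
import pandas as pd
import pytest

from heritpart.io import GenotypeMatrix


def make_snp_table(n_snps, chromosome="1", positions=None):
    return pd.DataFrame(
        {
            "snp_id": [f"snp{j}" for j in range(n_snps)],
            "chromosome": str(chromosome),
            "position_bp": positions if positions is not None
            else np.arange(1, n_snps + 1) * 1000,
            "counted_allele": "A",
            "other_allele": "B",
        }
    )


def make_genotypes(dosages, sample_ids=None, **kwargs):
    dosages = np.asarray(dosages, dtype=float)
    if sample_ids is None:
        sample_ids = [f"i{k}" for k in range(dosages.shape[0])]
    return GenotypeMatrix(dosages, sample_ids, make_snp_table(dosages.shape[1], **kwargs))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_panel(rng):
    """Complete random panel with common alleles, 12 individuals x 40 SNPs."""
    p = rng.uniform(0.2, 0.8, size=40)
    d = rng.binomial(2, p, size=(12, 40)).astype(float)
    # guard against monomorphic columns
    d[0] = 0.0
    d[1] = 2.0
    d[2] = 1.0
    return make_genotypes(d)
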