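import numpy as np
import pandas as pd
import pytest

from admixprs.io import GenotypeSet


def make_genotypes(
    dosage,
    positions=None,
    chrom="1",
    ref="A",
    alt="G",
    sample_ids=None,
    phased=None,
):
    """Small GenotypeSet builder for hand-constructed fixtures."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    if positions is None:
        positions = 1000 * (np.arange(m) + 1)
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j+1}" for j in range(m)],
            "chrom": chrom,
            "pos": positions,
            "ref": ref,
            "alt": alt,
        }
    )
    return GenotypeSet(
        sample_ids=sample_ids or [f"S{i+1}" for i in range(n)],
        variants=variants,
        dosage=dosage,
        phased=phased,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
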