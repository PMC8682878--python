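import numpy as np
import pandas as pd
import pytest

from lineagescan import GenotypeMatrix, SimulationConfig, simulate_cohort


def make_gm(dosage, positions=None, chrom="chr1", ad=None, dp=None, sample_ids=None):
    """Build a small GenotypeMatrix from a dosage array (samples x variants)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_samples, n_variants = dosage.shape
    if positions is None:
        positions = np.arange(1, n_variants + 1) * 100
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions),
            "ref": "A",
            "alt": "T",
            "n_alt": 1,
            "is_snp": True,
        }
    )
    return GenotypeMatrix(
        sample_ids=sample_ids or [f"s{i}" for i in range(n_samples)],
        variants=variants,
        dosage=dosage,
        allele_depths=None if ad is None else np.asarray(ad, dtype=np.int32),
        depth=None if dp is None else np.asarray(dp, dtype=np.int32),
    )


@pytest.fixture(scope="session")
def background_cohort():
    """A moderately sized two-lineage cohort with background divergence only."""
    return simulate_cohort(SimulationConfig(seed=11, n_variants=5000, target_fst=0.2))
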