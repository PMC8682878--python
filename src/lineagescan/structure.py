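"""Individual-level diversity and relatedness metrics.

Shared-allele percent between two diploids counts, per co-called site,
``2 - |d_i - d_j|`` shared alleles out of 2; identity-by-state
dissimilarity is its complement on the 0-1 scale. Hierarchical
clustering of the dissimilarity matrix orders samples for heatmaps and
dendrograms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .matrix import MISSING, GenotypeMatrix

__all__ = [
    "shared_allele_percent",
    "ibs_dissimilarity",
    "diversity_metrics",
    "hierarchical_cluster",
]

#: combined assembly length used to express het counts per kbp
DEFAULT_GENOME_SIZE_BP = 2_528_518_120


def _pairwise_shared(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(mean shared-allele fraction, co-called site count) per pair.

    Only sites called in both samples enter a pair's denominator; pairs
    with zero co-called sites are NaN.
    """
    d = gm.dosage.astype(np.float64)
    called = gm.dosage != MISSING
    d[~called] = 0.0
    c = called.astype(np.float64)
    # sum over co-called sites of |d_i - d_j| via the expansion
    # |a-b| for dosages in {0,1,2}: |a-b| = a + b - 2*min(a,b); min needs care,
    # so use the polynomial identity on the 3x3 dosage table instead:
    # |a-b| = (a-b)^2 - ab(a-2)(b-2)/... simpler to accumulate by dosage class.
    n_pairs_sites = c @ c.T
    abs_sum = np.zeros((gm.n_samples, gm.n_samples))
    for a in (0, 1, 2):
        for b in (0, 1, 2):
            if a == b:
                continue
            ia = ((gm.dosage == a) & called).astype(np.float64)
            ib = ((gm.dosage == b) & called).astype(np.float64)
            abs_sum += abs(a - b) * (ia @ ib.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        shared = np.where(n_pairs_sites > 0, 1.0 - abs_sum / (2.0 * n_pairs_sites), np.nan)
    return shared, n_pairs_sites.astype(int)


def shared_allele_percent(gm: GenotypeMatrix) -> pd.DataFrame:
    """Symmetric percent-shared-alleles matrix (diagonal 100)."""
    shared, _ = _pairwise_shared(gm)
    out = pd.DataFrame(100.0 * shared, index=gm.sample_ids, columns=gm.sample_ids)
    np.fill_diagonal(out.values, 100.0)
    return out


def ibs_dissimilarity(gm: GenotypeMatrix) -> pd.DataFrame:
    """1 - mean IBS fraction; equals ``1 - shared_allele_percent/100``."""
    shared, _ = _pairwise_shared(gm)
    out = pd.DataFrame(1.0 - shared, index=gm.sample_ids, columns=gm.sample_ids)
    np.fill_diagonal(out.values, 0.0)
    return out


def diversity_metrics(
    gm: GenotypeMatrix, genome_size_bp: int = DEFAULT_GENOME_SIZE_BP
) -> pd.DataFrame:
    """Per-sample heterozygosity metrics.

    het_ratio = n_het / n_hom_alt (NA when the sample has no hom-alt
    calls); het_per_kbp = n_het / genome_size_bp * 1000.
    """
    n_het = (gm.dosage == 1).sum(axis=1)
    n_hom_alt = (gm.dosage == 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(n_hom_alt > 0, n_het / np.maximum(n_hom_alt, 1), np.nan)
    return pd.DataFrame(
        {
            "sample_id": gm.sample_ids,
            "n_het": n_het,
            "n_hom_alt": n_hom_alt,
            "het_ratio": ratio,
            "het_per_kbp": n_het / genome_size_bp * 1000.0,
            "genome_size_bp": genome_size_bp,
        }
    )


def hierarchical_cluster(matrix: pd.DataFrame, linkage: str = "average"):
    """Agglomerative clustering of a symmetric dissimilarity matrix.

    Returns ``(linkage_matrix, leaf_order)`` where the leaf order is the
    scipy dendrogram order (deterministic for a given matrix; input rows
    should be sorted by sample id for a reproducible tie-break).
    """
    values = matrix.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1] or not np.allclose(
        values, values.T, atol=1e-10, equal_nan=True
    ):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    if np.isnan(values).any():
        raise ValueError("dissimilarity matrix contains NA cells")
    condensed = squareform(values, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    order = hierarchy.leaves_list(Z)
    return Z, [matrix.index[i] for i in order]
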