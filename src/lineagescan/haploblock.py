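"""Haploblock genotyping and Hardy-Weinberg testing.

Multi-megabase regions inherited as a single locus (centromeric
divergence blocks, deletion/fusion polymorphisms) leave a simple
signature in a genotype matrix: carriers of both block haplotypes are
heterozygous at essentially every segregating site in the region, while
homozygotes are homozygous throughout. Each sample is therefore called
AA/AB/BB from its per-region heterozygous and homozygous site
fractions, and the resulting genotype counts can be tested for
Hardy-Weinberg equilibrium with a chi-square goodness-of-fit test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import MISSING, GenotypeMatrix

__all__ = ["HWEResult", "genotype_haploblock", "block_allele_freq", "hwe_chisq"]


def genotype_haploblock(
    gm: GenotypeMatrix,
    region: tuple[str, int, int],
    min_sites: int = 50,
    het_ab_threshold: float = 0.5,
    hom_threshold: float = 0.8,
) -> pd.DataFrame:
    """Call AA/AB/BB per sample over a region (0-based half-open bp).

    AB when the heterozygous fraction of called sites reaches
    ``het_ab_threshold``; otherwise AA (hom-ref fraction >=
    ``hom_threshold``) or BB (hom-alt fraction >= ``hom_threshold``);
    ambiguous or under-covered samples (< ``min_sites`` called) are NA.
    """
    chrom, start, end = region
    mask = gm.region_mask(chrom, start, end)
    d = gm.dosage[:, mask]
    called = d != MISSING
    n_sites = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = (d == 1).sum(axis=1) / np.maximum(n_sites, 1)
        hom_ref = (d == 0).sum(axis=1) / np.maximum(n_sites, 1)
        hom_alt = (d == 2).sum(axis=1) / np.maximum(n_sites, 1)
    calls = np.full(gm.n_samples, "NA", dtype=object)
    ok = n_sites >= min_sites
    calls[ok & (het >= het_ab_threshold)] = "AB"
    calls[ok & (het < het_ab_threshold) & (hom_ref >= hom_threshold)] = "AA"
    calls[ok & (het < het_ab_threshold) & (hom_ref < hom_threshold) & (hom_alt >= hom_threshold)] = "BB"
    return pd.DataFrame(
        {
            "sample_id": gm.sample_ids,
            "chrom": chrom,
            "start": start,
            "end": end,
            "call": calls,
            "het_fraction": np.where(n_sites > 0, het, np.nan),
            "hom_alt_fraction": np.where(n_sites > 0, hom_alt, np.nan),
            "n_sites": n_sites,
        }
    )


def block_allele_freq(counts: tuple[int, int, int]) -> float:
    """Frequency of the A (reference) haplotype from (nAA, nAB, nBB):
    p = (2 nAA + nAB) / 2n."""
    n_aa, n_ab, n_bb = counts
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotyped sample required")
    return (2 * n_aa + n_ab) / (2 * n)


@dataclass
class HWEResult:
    observed: tuple[int, int, int]
    allele_freq_p: float
    expected: tuple[float, float, float]
    chi2: float
    df: int
    p_value: float
    monomorphic: bool = False


def hwe_chisq(counts: tuple[int, int, int], df: int = 2) -> HWEResult:
    """Chi-square goodness-of-fit of genotype counts to Hardy-Weinberg.

    Expected counts are (n p^2, 2 n p (1-p), n (1-p)^2) with p estimated
    from the counts. The default compares the three genotype classes
    against the fully specified HWE expectation (df = 2); pass ``df=1``
    for the convention that charges one degree of freedom for the
    estimated allele frequency. Monomorphic blocks (p in {0, 1}) return
    chi2 = 0, flagged.
    """
    n_aa, n_ab, n_bb = counts
    n = n_aa + n_ab + n_bb
    p = block_allele_freq(counts)
    if p in (0.0, 1.0):
        exp = (n * p**2, 2 * n * p * (1 - p), n * (1 - p) ** 2)
        return HWEResult(counts, p, exp, 0.0, df, 1.0, monomorphic=True)
    exp = (n * p**2, 2 * n * p * (1 - p), n * (1 - p) ** 2)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(counts, exp))
    return HWEResult(counts, p, exp, float(chi2), df, float(stats.chi2.sf(chi2, df)))
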