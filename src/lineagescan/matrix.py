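"""Core in-memory container: a samples x variants genotype matrix.

Every statistic in the package operates on :class:`GenotypeMatrix`, which
stores alt-allele dosages (0/1/2, -1 for missing) plus optional per-call
allele depths and total depths as parsed from VCF GT/AD/DP fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: columns every variant table carries; ``n_alt`` tracks multiallelic records
#: (kept at read time, removed by the hard filter), ``is_snp`` marks records
#: whose REF and all ALT alleles are single bases.
VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt", "n_alt", "is_snp")


@dataclass
class GenotypeMatrix:
    """Diploid genotypes for a cohort.

    Parameters
    ----------
    sample_ids : list of str
        Ordered sample names; rows of ``dosage``.
    variants : pandas.DataFrame
        One row per variant with at least ``chrom, pos, ref, alt``
        (``pos`` is 1-based, as in VCF). Sorted by (chrom, pos).
    dosage : ndarray of int8, shape (n_samples, n_variants)
        Count of alt alleles per call, ``-1`` when the genotype is
        missing (including half-calls such as ``0/.``).
    allele_depths : ndarray of int32, shape (n_samples, n_variants, 2), optional
        (ref reads, alt reads) per call, from the VCF AD field.
    depth : ndarray of int32, shape (n_samples, n_variants), optional
        Total read depth per call, from the VCF DP field.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray
    allele_depths: np.ndarray | None = None
    depth: np.ndarray | None = None
    metadata: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (self.n_samples, self.n_variants):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{self.n_samples} samples x {self.n_variants} variants"
            )
        missing = {"chrom", "pos", "ref", "alt"} - set(self.variants.columns)
        if missing:
            raise ValueError(f"variant table lacks columns: {sorted(missing)}")
        if "n_alt" not in self.variants.columns:
            self.variants = self.variants.assign(n_alt=1)
        if "is_snp" not in self.variants.columns:
            is_snp = (
                self.variants["ref"].str.len().eq(1)
                & self.variants["alt"].astype(str).str.split(",").map(
                    lambda a: all(len(x) == 1 for x in a)
                )
            )
            self.variants = self.variants.assign(is_snp=is_snp)
        self.variants = self.variants.reset_index(drop=True)
        pos = self.variants[["chrom", "pos"]]
        if not pos.equals(pos.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)):
            raise ValueError("variants must be sorted by (chrom, pos)")
        if self.allele_depths is not None:
            self.allele_depths = np.asarray(self.allele_depths, dtype=np.int32)
            if (self.allele_depths < 0).any():
                raise ValueError("allele depths must be nonnegative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of called genotypes, shape (n_samples, n_variants)."""
        return self.dosage != MISSING

    def allele_frequency(self) -> np.ndarray:
        """Alt-allele frequency per variant over called genotypes (NaN if none)."""
        called = self.called
        n_alleles = 2 * called.sum(axis=0)
        alt = np.where(called, self.dosage, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)

    def minor_allele_frequency(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        """Fraction of samples with a called genotype, per variant."""
        return self.called.mean(axis=0)

    def take_variants(self, index) -> "GenotypeMatrix":
        """Subset to the variants selected by a boolean mask or index array."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=self.variants.iloc[index],
            dosage=self.dosage[:, index],
            allele_depths=None if self.allele_depths is None else self.allele_depths[:, index],
            depth=None if self.depth is None else self.depth[:, index],
            metadata=self.metadata,
        )

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in index],
            variants=self.variants,
            dosage=self.dosage[index],
            allele_depths=None if self.allele_depths is None else self.allele_depths[index],
            depth=None if self.depth is None else self.depth[index],
            metadata=None if self.metadata is None else self.metadata.iloc[index],
        )

    def region_mask(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Mask of variants inside [start, end) (0-based half-open bp)."""
        pos0 = self.variants["pos"].to_numpy() - 1
        return (
            (self.variants["chrom"].to_numpy() == chrom)
            & (pos0 >= start)
            & (pos0 < end)
        )
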