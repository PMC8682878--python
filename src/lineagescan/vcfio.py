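"""VCF input/output and the three-stage variant filtering pipeline.

Filtering mirrors the standard re-sequencing workflow for a two-lineage
cohort: (1) hard filters (biallelic SNPs, minor-allele frequency, call
rate), (2) an allele-balance filter that drops variants whose pooled
heterozygous read counts are skewed toward one allele (a signature of
mis-mapped paralogous reads), and (3) greedy LD thinning within a
physical window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .matrix import MISSING, GenotypeMatrix

__all__ = [
    "FilterParams",
    "read_vcf",
    "write_vcf",
    "hard_filter",
    "allele_balance_filter",
    "ld_thin",
    "apply_all_filters",
]


@dataclass
class FilterParams:
    """Thresholds for the three filtering stages.

    Defaults follow the conventional hard-filter set for cohort
    re-sequencing data: MAF >= 0.05 (boundary inclusive), call rate >=
    0.9, biallelic SNPs only; allele-balance minimum minor/major read
    ratio 0.20 (strict inequality drops); LD thinning with a 20 kbp
    window, r^2 > 0.4 prunes, at most 2 kept variants per window.
    """

    maf_min: float = 0.05
    max_missing_kept: float = 0.9
    biallelic_only: bool = True
    snps_only: bool = True
    ab_min_fraction: float = 0.20
    ld_window_bp: int = 20_000
    ld_r2_max: float = 0.4
    ld_max_keep: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if not 0 <= self.ab_min_fraction <= 1:
            raise ValueError("ab_min_fraction must be in [0, 1]")
        if self.ld_max_keep < 1:
            raise ValueError("ld_max_keep must be >= 1")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    GT is required; AD and DP are used when present. Phasing is ignored
    (``0|1`` equals ``0/1``); half-calls (``0/.``) are treated as
    missing. Multiallelic records are preserved (one column, alt-1
    dosage) so that the hard filter can log their removal.
    """
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    rows, dosages, ads, dps = [], [], [], []
    has_ad = has_dp = True
    for line_no, v in enumerate(vcf, start=1):
        gts = np.asarray([g[:2] for g in v.genotypes], dtype=np.int32)
        if gts.shape[1] != 2:
            raise ValueError(f"record {line_no} ({v.CHROM}:{v.POS}): non-diploid GT")
        dose = np.where((gts < 0).any(axis=1), MISSING, (gts == 1).sum(axis=1))
        dosages.append(dose.astype(np.int8))
        alt = ",".join(v.ALT) if v.ALT else "."
        is_snp = len(v.REF) == 1 and all(len(a) == 1 for a in v.ALT)
        rows.append((v.CHROM, v.POS, v.REF, alt, len(v.ALT), is_snp))
        if has_ad:
            try:
                ad = v.format("AD")
            except KeyError:  # AD not declared in the header
                ad = None
            if ad is None:
                has_ad = bool(ads)  # AD absent from the start: drop it
                if ads:
                    raise ValueError(f"record {line_no}: AD present in some records only")
            else:
                ads.append(np.clip(ad[:, :2], 0, None).astype(np.int32))
        if has_dp:
            try:
                dp = v.format("DP")
            except KeyError:
                dp = None
            if dp is None:
                has_dp = bool(dps)
                if dps:
                    raise ValueError(f"record {line_no}: DP present in some records only")
            else:
                dps.append(np.clip(dp[:, 0], 0, None).astype(np.int32))
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "n_alt", "is_snp"])
    n = len(variants)
    return GenotypeMatrix(
        sample_ids=samples,
        variants=variants,
        dosage=(
            np.stack(dosages, axis=1) if n else np.empty((len(samples), 0), dtype=np.int8)
        ),
        allele_depths=np.stack(ads, axis=1) if has_ad and ads else None,
        depth=np.stack(dps, axis=1) if has_dp and dps else None,
    )


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a VCF v4.2 with GT[:AD[:DP]] calls (uncompressed text)."""
    fmt_keys = ["GT"]
    if gm.allele_depths is not None:
        fmt_keys.append("AD")
    if gm.depth is not None:
        fmt_keys.append("DP")
    fmt = ":".join(fmt_keys)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if gm.allele_depths is not None:
            fh.write(
                '##FORMAT=<ID=AD,Number=R,Type=Integer,'
                'Description="Allelic depths for the ref and alt alleles">\n'
            )
        if gm.depth is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in gm.variants["chrom"].unique():
            length = int(gm.variants.loc[gm.variants["chrom"] == chrom, "pos"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, row in enumerate(gm.variants.itertuples(index=False)):
            fields = [row.chrom, str(row.pos), ".", row.ref, row.alt, ".", "PASS", ".", fmt]
            for i in range(gm.n_samples):
                call = [gt_str[int(gm.dosage[i, j])]]
                if gm.allele_depths is not None:
                    call.append(f"{gm.allele_depths[i, j, 0]},{gm.allele_depths[i, j, 1]}")
                if gm.depth is not None:
                    call.append(str(gm.depth[i, j]))
                fields.append(":".join(call))
            fh.write("\t".join(fields) + "\n")


def _log(gm: GenotypeMatrix, stage: str, kept: np.ndarray, reasons: list[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": gm.variants["chrom"],
            "pos": gm.variants["pos"],
            "stage": stage,
            "kept": np.where(kept, "kept", "dropped"),
            "reason": reasons,
        }
    )


def hard_filter(
    gm: GenotypeMatrix, params: FilterParams | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Keep biallelic SNPs with MAF >= maf_min (inclusive) and call rate
    >= max_missing_kept. Returns the filtered matrix and a per-record
    disposition log."""
    params = params or FilterParams()
    n = gm.n_variants
    if n == 0:
        return gm, _log(gm, "hard", np.zeros(0, dtype=bool), [])
    keep = np.ones(n, dtype=bool)
    reasons = np.full(n, "pass", dtype=object)
    if params.biallelic_only:
        bad = gm.variants["n_alt"].to_numpy() != 1
        reasons[bad & keep] = "multiallelic"
        keep &= ~bad
    if params.snps_only:
        bad = ~gm.variants["is_snp"].to_numpy()
        reasons[bad & keep] = "not_snp"
        keep &= ~bad
    maf = gm.minor_allele_frequency()
    bad = ~(maf >= params.maf_min)  # NaN (all-missing) fails too
    reasons[bad & keep] = "maf"
    keep &= ~bad
    bad = gm.call_rate() < params.max_missing_kept
    reasons[bad & keep] = "call_rate"
    keep &= ~bad
    return gm.take_variants(keep), _log(gm, "hard", keep, list(reasons))


def allele_balance_filter(
    gm: GenotypeMatrix, ab_min_fraction: float = 0.20
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop variants whose heterozygous read counts, pooled across all
    het calls at the site, have minor/major ratio strictly below
    ``ab_min_fraction``.

    A genuine heterozygous site samples both alleles ~equally, so the
    pooled ratio sits near 1; collapsed paralogs and other artifacts
    show a strong skew. Records with no het calls, or with AD absent on
    every het call, are kept (the latter flagged ``untestable``).
    """
    n = gm.n_variants
    if gm.allele_depths is None:
        keep = np.ones(n, dtype=bool)
        return gm, _log(gm, "allele_balance", keep, ["untestable"] * n)
    het = gm.dosage == 1
    ref_sum = np.where(het[..., None], gm.allele_depths, 0)[:, :, 0].sum(axis=0)
    alt_sum = np.where(het[..., None], gm.allele_depths, 0)[:, :, 1].sum(axis=0)
    total = ref_sum + alt_sum
    has_het = het.any(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.minimum(ref_sum, alt_sum) / np.maximum(np.maximum(ref_sum, alt_sum), 1)
    testable = has_het & (total > 0)
    drop = testable & (ratio < ab_min_fraction)
    keep = ~drop
    reasons = np.full(n, "pass", dtype=object)
    reasons[~has_het] = "no_het_calls"
    reasons[has_het & (total == 0)] = "untestable"
    reasons[drop] = "allele_balance"
    return gm.take_variants(keep), _log(gm, "allele_balance", keep, list(reasons))


def _r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared genotype correlation over samples called at both sites;
    0 when either site is monomorphic among the shared samples."""
    both = (a != MISSING) & (b != MISSING)
    if both.sum() < 2:
        return 0.0
    x = a[both].astype(float)
    y = b[both].astype(float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
    return float(r * r)


def ld_thin(
    gm: GenotypeMatrix,
    window_bp: int = 20_000,
    r2_max: float = 0.4,
    max_keep: int = 2,
) -> GenotypeMatrix:
    """Greedy left-to-right LD thinning per chromosome.

    A candidate is dropped if its r^2 with any already-kept variant
    within ``window_bp`` exceeds ``r2_max``, or if ``max_keep`` kept
    variants already sit within ``window_bp`` of it. Deterministic
    given the (position-sorted) input order.
    """
    chroms = gm.variants["chrom"].to_numpy()
    pos = gm.variants["pos"].to_numpy()
    keep_idx: list[int] = []
    kept_by_chrom: dict[str, list[int]] = {}
    for j in range(gm.n_variants):
        kept = kept_by_chrom.setdefault(chroms[j], [])
        in_window = [k for k in kept if pos[j] - pos[k] <= window_bp]
        if len(in_window) >= max_keep:
            continue
        if any(_r2(gm.dosage[:, j], gm.dosage[:, k]) > r2_max for k in in_window):
            continue
        kept.append(j)
        keep_idx.append(j)
    return gm.take_variants(np.asarray(keep_idx, dtype=int))


def apply_all_filters(
    gm: GenotypeMatrix, params: FilterParams | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Hard filter, then allele-balance filter, then LD thinning."""
    params = params or FilterParams()
    gm1, log1 = hard_filter(gm, params)
    gm2, log2 = allele_balance_filter(gm1, params.ab_min_fraction)
    gm3 = ld_thin(gm2, params.ld_window_bp, params.ld_r2_max, params.ld_max_keep)
    return gm3, pd.concat([log1, log2], ignore_index=True)
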