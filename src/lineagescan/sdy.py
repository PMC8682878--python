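"""Sex-locus analytics: sdY copy number, haplotype typing, runs of
het/homozygosity, and a sex-association scan.

In salmonids the master sex-determining gene sdY is male-specific;
its copy number per sample is estimated as the ratio of the mean read
depth over designated sdY marker sites to the genome-wide mean depth
over all retained variants, with a ratio of 1.5 or greater taken as
evidence of a second copy. Two sdY haplotypes are typed from four
designated non-coding sites (the CGGA and TTAC patterns).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import MISSING, GenotypeMatrix

__all__ = [
    "CopyNumberEstimate",
    "estimate_copy_number",
    "call_sdy_haplotype",
    "heterozygosity_runs",
    "sex_association_scan",
]


@dataclass
class CopyNumberEstimate:
    sample_id: str
    mean_sdy_depth: float
    genome_mean_depth: float
    ratio: float
    multi_copy: bool
    estimated_copies: int
    sdy_haplotype: str = "NA"


def estimate_copy_number(
    sdy_depths,
    genome_mean_depth: float,
    sample_id: str = "sample",
    threshold: float = 1.5,
) -> CopyNumberEstimate:
    """sdY copy number from the depth ratio.

    ratio = mean(depth at sdY sites) / genome mean depth; ``multi_copy``
    when the ratio reaches ``threshold``; the integer copy count (ratio
    rounded) is for display only. All-zero sdY depth gives ratio 0 —
    absence of the gene, the female-typical state.
    """
    if genome_mean_depth <= 0:
        raise ValueError("genome_mean_depth must be positive")
    sdy_depths = np.asarray(sdy_depths, dtype=float)
    if sdy_depths.size == 0:
        raise ValueError("at least one sdY site depth required")
    mean_sdy = float(sdy_depths.mean())
    ratio = mean_sdy / genome_mean_depth
    return CopyNumberEstimate(
        sample_id=sample_id,
        mean_sdy_depth=mean_sdy,
        genome_mean_depth=float(genome_mean_depth),
        ratio=ratio,
        multi_copy=ratio >= threshold,
        estimated_copies=int(round(ratio)),
    )


def call_sdy_haplotype(dosages, min_called: int = 3) -> str:
    """Type the sdY haplotype from the four designated sites.

    Dosages are relative to the pattern-A (CGGA) allele coded as
    reference: all-hom-ref -> "CGGA", all-hom-alt -> "TTAC", any
    heterozygous or discordant site -> "mixed", fewer than
    ``min_called`` called sites -> "NA".
    """
    d = np.asarray(dosages)
    called = d[d != MISSING]
    if len(called) < min_called:
        return "NA"
    if (called == 0).all():
        return "CGGA"
    if (called == 2).all():
        return "TTAC"
    return "mixed"


def heterozygosity_runs(
    gm: GenotypeMatrix,
    region: tuple[str, int, int],
    window_sites: int = 25,
    het_run_min: float = 0.6,
    hom_run_max: float = 0.1,
) -> pd.DataFrame:
    """Label per-sample segments of a region as runs of het/homozygosity.

    A sliding window of ``window_sites`` consecutive variants is
    labeled ``het-run`` when its heterozygous fraction (of called
    sites) is >= ``het_run_min``, ``hom-run`` when <= ``hom_run_max``,
    else ``mixed``; adjacent same-label windows merge into segments.
    Near a sex locus, X/Y-heterogametic males show het-runs where
    females show hom-runs.
    """
    chrom, start, end = region
    mask = gm.region_mask(chrom, start, end)
    pos = gm.variants["pos"].to_numpy()[mask]
    d = gm.dosage[:, mask]
    n_region = d.shape[1]
    if n_region < window_sites:
        return pd.DataFrame(
            columns=["sample_id", "chrom", "start", "end", "label", "n_windows", "het_fraction"]
        )
    rows = []
    for i, sample in enumerate(gm.sample_ids):
        labels, spans, fracs = [], [], []
        for w0 in range(0, n_region - window_sites + 1, window_sites):
            win = d[i, w0 : w0 + window_sites]
            called = win != MISSING
            if called.sum() == 0:
                lab, frac = "NA", np.nan
            else:
                frac = (win == 1).sum() / called.sum()
                lab = "het-run" if frac >= het_run_min else "hom-run" if frac <= hom_run_max else "mixed"
            labels.append(lab)
            spans.append((int(pos[w0]), int(pos[min(w0 + window_sites, n_region) - 1])))
            fracs.append(frac)
        # merge adjacent same-label windows
        seg_start = 0
        for k in range(1, len(labels) + 1):
            if k == len(labels) or labels[k] != labels[seg_start]:
                rows.append(
                    {
                        "sample_id": sample,
                        "chrom": chrom,
                        "start": spans[seg_start][0],
                        "end": spans[k - 1][1],
                        "label": labels[seg_start],
                        "n_windows": k - seg_start,
                        "het_fraction": float(np.nanmean(fracs[seg_start:k])),
                    }
                )
                seg_start = k
    return pd.DataFrame(rows)


def sex_association_scan(gm: GenotypeMatrix, sex_labels) -> pd.DataFrame:
    """Allelic chi-square scan of genotype against sex.

    Per SNP, a 2x2 allele-count table (ref/alt x male/female) is tested
    with the continuity-corrected chi-square, falling back to Fisher's
    exact test when any expected cell is below 5. Monomorphic SNPs are
    skipped. The Bonferroni-corrected 0.05 threshold over tested SNPs
    is attached as ``DataFrame.attrs['bonferroni_0.05']``.
    """
    sex = np.asarray(sex_labels)
    if len(sex) != gm.n_samples:
        raise ValueError("sex_labels length must equal n_samples")
    levels = pd.unique(sex)
    if len(levels) != 2:
        raise ValueError("both sexes must be present")
    g1 = gm.dosage[sex == levels[0]]
    g2 = gm.dosage[sex == levels[1]]
    rows = []
    for j in range(gm.n_variants):
        a = g1[:, j][g1[:, j] != MISSING]
        b = g2[:, j][g2[:, j] != MISSING]
        alt1, ref1 = int(a.sum()), int(2 * len(a) - a.sum())
        alt2, ref2 = int(b.sum()), int(2 * len(b) - b.sum())
        if alt1 + alt2 == 0 or ref1 + ref2 == 0:
            continue  # monomorphic
        table = np.array([[ref1, alt1], [ref2, alt2]])
        expected = stats.contingency.expected_freq(table)
        if (expected < 5).any():
            _, p = stats.fisher_exact(table)
        else:
            _, p, _, _ = stats.chi2_contingency(table, correction=True)
        rows.append(
            {
                "chrom": gm.variants["chrom"].iat[j],
                "pos": int(gm.variants["pos"].iat[j]),
                "p_value": float(p),
            }
        )
    out = pd.DataFrame(rows, columns=["chrom", "pos", "p_value"])
    out.attrs["bonferroni_0.05"] = 0.05 / len(out) if len(out) else np.nan
    return out
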