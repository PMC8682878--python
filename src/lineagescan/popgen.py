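"""Windowed divergence and diversity statistics between two lineages.

Fst uses Hudson's estimator combined per window as a ratio of sums
("ratio of averages"), the standard choice for two-population genome
scans: per site, with allele frequencies p1, p2 estimated from n1, n2
called alleles,

    num = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)

and the window Fst is sum(num)/sum(den). Nucleotide diversity pi and
between-population diversity dxy are per-site sums divided by the
window length in bp (monomorphic positions contribute zero; the window
length denominates). Tajima's D follows the 1989 normalization with
each diploid contributing two sequences.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix

__all__ = [
    "pop_indices",
    "site_allele_stats",
    "hudson_fst_components",
    "window_stats",
    "window_fst",
    "window_diversity",
    "tajimas_d",
    "detect_fst_peaks",
    "population_summary",
]


def pop_indices(gm: GenotypeMatrix, pop_labels) -> dict[str, np.ndarray]:
    """Map each population label to its sample index array."""
    labels = np.asarray(pop_labels)
    if len(labels) != gm.n_samples:
        raise ValueError("pop_labels length must equal n_samples")
    return {p: np.flatnonzero(labels == p) for p in pd.unique(labels)}


def site_allele_stats(gm: GenotypeMatrix, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (called allele count, alt frequency) within one population."""
    d = gm.dosage[idx]
    called = d != -1
    n_alleles = 2 * called.sum(axis=0)
    alt = np.where(called, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    return n_alleles, p


def hudson_fst_components(
    n1: np.ndarray, p1: np.ndarray, n2: np.ndarray, p2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Hudson numerator/denominator; NaN where a population has
    fewer than two called alleles."""
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / np.maximum(n1 - 1, 1)
            - p2 * (1 - p2) / np.maximum(n2 - 1, 1)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
    bad = (n1 < 2) | (n2 < 2) | np.isnan(p1) | np.isnan(p2)
    num = np.where(bad, np.nan, num)
    den = np.where(bad, np.nan, den)
    return num, den


def _tajima_constants(n: int) -> tuple[float, float]:
    """(a1, sqrt-normalization pieces e1, e2) for sample size n sequences."""
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajimas_d(gm: GenotypeMatrix, idx: np.ndarray, site_mask: np.ndarray | None = None) -> float:
    """Tajima's D for one population over the selected sites.

    Each diploid contributes two sequences; sites with missing calls use
    their own called allele count for the pairwise-diversity term, and
    the normalization constants use the mean called count across
    segregating sites (rounded). NA (NaN) when there are no segregating
    sites or fewer than four called sequences.
    """
    if site_mask is None:
        site_mask = np.ones(gm.n_variants, dtype=bool)
    sub = gm.take_samples(idx).take_variants(site_mask)
    n_alleles, p = site_allele_stats(sub, np.arange(sub.n_samples))
    seg = (n_alleles >= 2) & (p > 0) & (p < 1)
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    n = int(round(n_alleles[seg].mean()))
    if n < 4:
        return float("nan")
    ns = n_alleles[seg]
    pi_hat = float(np.sum(2 * p[seg] * (1 - p[seg]) * ns / (ns - 1)))
    a1, e1, e2 = _tajima_constants(n)
    theta_w = S / a1
    denom = np.sqrt(e1 * S + e2 * S * (S - 1))
    if denom == 0:
        return float("nan")
    return (pi_hat - theta_w) / denom


def window_stats(
    gm: GenotypeMatrix,
    pop_labels,
    window_bp: int = 10_000,
    step_bp: int | None = None,
) -> pd.DataFrame:
    """Per-window Fst, pi (per population), dxy, Tajima's D (per population).

    Windows are 0-based half-open tiles of ``window_bp`` (``step_bp``
    defaults to ``window_bp``, i.e. non-overlapping). Statistics are NA
    where a window has no usable site.
    """
    step_bp = step_bp or window_bp
    pops = pop_indices(gm, pop_labels)
    if len(pops) != 2:
        raise ValueError("window statistics require exactly two populations")
    (name1, idx1), (name2, idx2) = pops.items()
    n1, p1 = site_allele_stats(gm, idx1)
    n2, p2 = site_allele_stats(gm, idx2)
    num, den = hudson_fst_components(n1, p1, n2, p2)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi1_site = np.where(n1 >= 2, 2 * p1 * (1 - p1) * n1 / np.maximum(n1 - 1, 1), np.nan)
        pi2_site = np.where(n2 >= 2, 2 * p2 * (1 - p2) * n2 / np.maximum(n2 - 1, 1), np.nan)
        dxy_site = np.where((n1 >= 1) & (n2 >= 1), p1 * (1 - p2) + p2 * (1 - p1), np.nan)

    rows = []
    chroms = gm.variants["chrom"].to_numpy()
    pos0 = gm.variants["pos"].to_numpy() - 1
    for chrom in pd.unique(chroms):
        on = chroms == chrom
        cpos = pos0[on]
        last = int(cpos.max())
        for start in range(0, last + 1, step_bp):
            end = start + window_bp
            w = on & (pos0 >= start) & (pos0 < end)
            usable = w & ~np.isnan(den)
            n_snps = int(usable.sum())
            if n_snps == 0:
                rows.append((chrom, start, end, 0, *([np.nan] * 6)))
                continue
            den_sum = np.nansum(den[usable])
            fst = np.nansum(num[usable]) / den_sum if den_sum > 0 else np.nan
            pi_1 = np.nansum(pi1_site[usable]) / window_bp
            pi_2 = np.nansum(pi2_site[usable]) / window_bp
            dxy = np.nansum(dxy_site[usable]) / window_bp
            d1 = tajimas_d(gm, idx1, usable)
            d2 = tajimas_d(gm, idx2, usable)
            rows.append((chrom, start, end, n_snps, fst, pi_1, pi_2, dxy, d1, d2))
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "n_snps",
            "fst",
            f"pi_{name1}",
            f"pi_{name2}",
            "dxy",
            f"tajd_{name1}",
            f"tajd_{name2}",
        ],
    )


def window_fst(gm, pop_labels, window_bp: int = 10_000, step_bp: int | None = None) -> pd.DataFrame:
    return window_stats(gm, pop_labels, window_bp, step_bp)[
        ["chrom", "start", "end", "n_snps", "fst"]
    ]


def window_diversity(
    gm, pop_labels, window_bp: int = 10_000, step_bp: int | None = None
) -> pd.DataFrame:
    df = window_stats(gm, pop_labels, window_bp, step_bp)
    return df[[c for c in df.columns if not c.startswith("tajd") and c != "fst"]]


def detect_fst_peaks(
    windows: pd.DataFrame,
    fst_threshold: float = 0.25,
    highlight_threshold: float = 0.5,
    max_gap_windows: int = 1,
) -> pd.DataFrame:
    """Merge consecutive above-threshold windows into Fst peaks.

    Up to ``max_gap_windows`` consecutive below-threshold (or NA)
    windows are tolerated inside a peak; trailing gaps are trimmed.
    Reports bp extent, member-window count, mean and max Fst over
    member windows, and whether the max exceeds the highlight level.
    """
    peaks = []
    for chrom, cdf in windows.groupby("chrom", sort=False):
        cdf = cdf.sort_values("start")
        members: list[pd.Series] = []
        gap = 0
        for _, w in cdf.iterrows():
            above = pd.notna(w["fst"]) and w["fst"] > fst_threshold
            if above:
                members.append(w)
                gap = 0
            elif members:
                gap += 1
                if gap > max_gap_windows:
                    peaks.append((chrom, members))
                    members, gap = [], 0
        if members:
            peaks.append((chrom, members))
    rows = []
    for chrom, members in peaks:
        fsts = np.array([w["fst"] for w in members])
        rows.append(
            {
                "chrom": chrom,
                "start": int(members[0]["start"]),
                "end": int(members[-1]["end"]),
                "n_windows": len(members),
                "size_bp": int(members[-1]["end"] - members[0]["start"]),
                "mean_fst": float(fsts.mean()),
                "max_fst": float(fsts.max()),
                "highlighted": bool(fsts.max() > highlight_threshold),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "n_windows",
            "size_bp",
            "mean_fst",
            "max_fst",
            "highlighted",
        ],
    )


def population_summary(gm: GenotypeMatrix, pop_labels) -> pd.DataFrame:
    """Per-population diversity summary over the retained variants:
    variant count, % polymorphic, private alleles, mean per-variant pi,
    and mean Fis over polymorphic variants (1 - Hobs/Hexp)."""
    pops = pop_indices(gm, pop_labels)
    if any(len(idx) == 0 for idx in pops.values()):
        raise ValueError("every population must contain at least one sample")
    stats_by_pop = {}
    presence = {}  # pop -> (ref present, alt present) per variant
    for name, idx in pops.items():
        n_alleles, p = site_allele_stats(gm, idx)
        d = gm.dosage[idx]
        called = d != -1
        n_called = called.sum(axis=0)
        hobs = np.where(n_called > 0, (d == 1).sum(axis=0) / np.maximum(n_called, 1), np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            hexp = 2 * p * (1 - p) * n_alleles / np.maximum(n_alleles - 1, 1)
        poly = (n_alleles >= 2) & (p > 0) & (p < 1)
        fis_site = 1 - hobs[poly] / hexp[poly]
        stats_by_pop[name] = {
            "n_variants": gm.n_variants,
            "pct_polymorphic": 100.0 * poly.mean() if gm.n_variants else np.nan,
            "pi": float(np.nanmean(np.where(n_alleles >= 2, hexp, np.nan))),
            "fis": float(np.mean(fis_site)) if poly.any() else np.nan,
        }
        presence[name] = ((p < 1) & (n_alleles > 0), (p > 0) & (n_alleles > 0))
    for name in pops:
        other_ref = np.any([presence[o][0] for o in pops if o != name], axis=0)
        other_alt = np.any([presence[o][1] for o in pops if o != name], axis=0)
        private = (presence[name][0] & ~other_ref).sum() + (presence[name][1] & ~other_alt).sum()
        stats_by_pop[name]["private_alleles"] = int(private)
    out = pd.DataFrame(stats_by_pop).T
    out.index.name = "population"
    return out[["n_variants", "pct_polymorphic", "private_alleles", "pi", "fis"]]
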