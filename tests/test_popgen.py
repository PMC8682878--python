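"""Windowed Fst/pi/dxy/Tajima's D against hand computations and
brute-force oracles, plus peak detection and population summaries."""

import numpy as np
import pytest

from lineagescan import (
    MISSING,
    SimulationConfig,
    detect_fst_peaks,
    population_summary,
    simulate_cohort,
    window_stats,
)
from lineagescan.popgen import (
    hudson_fst_components,
    pop_indices,
    site_allele_stats,
    tajimas_d,
)
from tests.conftest import make_gm


def brute_force_window_fst(gm, labels, window_bp):
    """Per-site Hudson components recomputed with scalar arithmetic."""
    labels = np.asarray(labels)
    results = {}
    pos0 = gm.variants["pos"].to_numpy() - 1
    pops = [np.flatnonzero(labels == p) for p in dict.fromkeys(labels)]
    for start in range(0, int(pos0.max()) + 1, window_bp):
        nums, dens = [], []
        for j in np.flatnonzero((pos0 >= start) & (pos0 < start + window_bp)):
            stats = []
            for idx in pops:
                d = gm.dosage[idx, j]
                d = d[d != MISSING]
                n = 2 * len(d)
                stats.append((n, d.sum() / n if n else np.nan))
            (n1, p1), (n2, p2) = stats
            if n1 < 2 or n2 < 2:
                continue
            nums.append((p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1))
            dens.append(p1 * (1 - p2) + p2 * (1 - p1))
        if dens and sum(dens) > 0:
            results[start] = sum(nums) / sum(dens)
    return results


class TestHudsonFst:
    def test_hand_evaluated_single_site(self):
        # both pops n=4 alleles, p1=p2=0.5 -> num=-1/6, den=0.5, Fst=-1/3
        dosage = np.array([[1], [1], [1], [1]], dtype=np.int8)
        gm = make_gm(dosage)
        labels = ["a", "a", "b", "b"]
        w = window_stats(gm, labels, window_bp=10_000)
        assert w["fst"].iloc[0] == pytest.approx(-1 / 3)

    def test_fixed_differences_give_fst_one(self):
        dosage = np.array([[0] * 5, [0] * 5, [2] * 5, [2] * 5], dtype=np.int8)
        gm = make_gm(dosage)
        w = window_stats(gm, ["a", "a", "b", "b"], window_bp=10_000)
        assert w["fst"].iloc[0] == pytest.approx(1.0)

    def test_null_split_of_one_population_gives_zero_fst(self):
        sim = simulate_cohort(SimulationConfig(seed=53, n_odd=60, n_even=0,
                                               n_variants=10_000, target_fst=0.0))
        labels = ["a" if i % 2 == 0 else "b" for i in range(60)]
        n1, p1 = site_allele_stats(sim.gm, np.arange(0, 60, 2))
        n2, p2 = site_allele_stats(sim.gm, np.arange(1, 60, 2))
        num, den = hudson_fst_components(n1, p1, n2, p2)
        assert abs(np.nansum(num) / np.nansum(den)) < 0.02

    def test_matches_brute_force_oracle_on_simulated_cohort(self, background_cohort):
        gm = background_cohort.gm
        labels = background_cohort.metadata["lineage"].to_numpy()
        w = window_stats(gm, labels, window_bp=1_000_000)
        oracle = brute_force_window_fst(gm, labels, 1_000_000)
        checked = 0
        for _, row in w.iterrows():
            if row["start"] in oracle and not np.isnan(row["fst"]):
                assert row["fst"] == pytest.approx(oracle[row["start"]], abs=1e-12)
                checked += 1
        assert checked >= 5

    def test_fst_never_exceeds_one(self, background_cohort):
        w = window_stats(
            background_cohort.gm,
            background_cohort.metadata["lineage"],
            window_bp=100_000,
        )
        assert (w["fst"].dropna() <= 1.0 + 1e-12).all()


class TestDiversity:
    def test_monomorphic_window_has_zero_pi_and_dxy(self):
        dosage = np.zeros((4, 5), dtype=np.int8)
        gm = make_gm(dosage)
        w = window_stats(gm, ["a", "a", "b", "b"], window_bp=10_000)
        assert w["pi_a"].iloc[0] == 0 and w["pi_b"].iloc[0] == 0 and w["dxy"].iloc[0] == 0

    def test_single_segregating_site_pi_formula(self):
        # p=0.5, n=4 alleles, window 10 kbp -> pi = (2*0.25*4/3)/10000
        dosage = np.array([[1], [1], [0], [0]], dtype=np.int8)
        gm = make_gm(dosage)
        w = window_stats(gm, ["a", "a", "b", "b"], window_bp=10_000)
        assert w["pi_a"].iloc[0] == pytest.approx(2 * 0.25 * (4 / 3) / 10_000)

    def test_dxy_matches_pairwise_difference_oracle(self, background_cohort):
        """dxy equals the brute-force mean per-site difference fraction
        between all cross-population sequence pairs."""
        gm = background_cohort.gm.take_variants(np.arange(200))
        labels = background_cohort.metadata["lineage"].to_numpy()
        idx1 = np.flatnonzero(labels == "odd")
        idx2 = np.flatnonzero(labels == "even")
        window_bp = int(gm.variants["pos"].max())  # one window spanning all sites
        w = window_stats(gm, labels, window_bp=window_bp)
        total = 0.0
        for j in range(gm.n_variants):
            d1 = gm.dosage[idx1, j]
            d2 = gm.dosage[idx2, j]
            d1, d2 = d1[d1 != MISSING], d2[d2 != MISSING]
            # expand diploids into allele multisets; average pairwise diff
            a1 = np.concatenate([[1] * d + [0] * (2 - d) for d in d1])
            a2 = np.concatenate([[1] * d + [0] * (2 - d) for d in d2])
            total += np.abs(a1[:, None] - a2[None, :]).mean()
        used = w[w["n_snps"] > 0]
        dxy_sum = (used["dxy"] * window_bp).sum()
        assert dxy_sum == pytest.approx(total, rel=1e-9)

    def test_dxy_nonnegative(self, background_cohort):
        w = window_stats(
            background_cohort.gm,
            background_cohort.metadata["lineage"],
            window_bp=500_000,
        )
        assert (w["dxy"].dropna() >= 0).all()


class TestTajimasD:
    def test_no_segregating_sites_is_na(self):
        gm = make_gm(np.zeros((4, 3), dtype=np.int8))
        assert np.isnan(tajimas_d(gm, np.arange(4)))

    def test_singleton_site_matches_hand_constants(self):
        # n=4 sequences (2 diploids), one singleton: pi=0.5, thetaW=6/11
        dosage = np.array([[1], [0]], dtype=np.int8)
        gm = make_gm(dosage)
        d = tajimas_d(gm, np.arange(2))
        a1 = 1 + 1 / 2 + 1 / 3
        assert a1 == pytest.approx(11 / 6)
        pi_hat, theta_w = 0.5, 1 / a1
        assert d < 0
        # reproduce the normalization by hand
        n, S = 4, 1
        a2 = 1 + 1 / 4 + 1 / 9
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a1**2 + a2)
        expect = (pi_hat - theta_w) / np.sqrt(e1 * S + e2 * S * (S - 1))
        assert d == pytest.approx(expect)

    def test_zero_when_pi_equals_watterson(self):
        # At n=4 sequences a singleton contributes pi 1/2 and a doubleton
        # 2/3, while each segregating site adds 6/11 to S/a1; 8 singletons
        # plus 3 doubletons makes both sides exactly 6, so D = 0.
        cols = [[1, 0]] * 8 + [[2, 0]] * 3
        gm = make_gm(np.array(cols, dtype=np.int8).T)
        assert tajimas_d(gm, np.arange(2)) == pytest.approx(0.0, abs=1e-12)

    def test_negative_after_sweep_like_excess_of_rare_alleles(self):
        rng = np.random.default_rng(59)
        # 30 diploids, many singletons -> D < 0
        dosage = np.zeros((30, 200), dtype=np.int8)
        for j in range(200):
            dosage[rng.integers(0, 30), j] = 1
        gm = make_gm(dosage)
        assert tajimas_d(gm, np.arange(30)) < 0


class TestPeaks:
    def windows(self, fsts, window_bp=10_000):
        import pandas as pd

        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(len(fsts)) * window_bp,
                "end": (np.arange(len(fsts)) + 1) * window_bp,
                "n_snps": 5,
                "fst": fsts,
            }
        )

    def test_no_window_above_threshold_gives_empty(self):
        peaks = detect_fst_peaks(self.windows([0.1, 0.2, 0.05]))
        assert len(peaks) == 0

    def test_contiguous_run_merges_into_single_sized_peak(self):
        fsts = [0.1] + [0.6] * 300 + [0.1]
        peaks = detect_fst_peaks(self.windows(fsts))
        assert len(peaks) == 1
        assert peaks["size_bp"].iloc[0] == 300 * 10_000  # ~3 Mbp
        assert peaks["highlighted"].iloc[0]

    def test_gap_longer_than_max_gap_splits_peaks(self):
        fsts = [0.6] * 3 + [0.1] * 5 + [0.6] * 3
        peaks = detect_fst_peaks(self.windows(fsts), max_gap_windows=1)
        assert len(peaks) == 2

    def test_single_gap_window_bridged(self):
        fsts = [0.6, 0.6, 0.1, 0.6, 0.6]
        peaks = detect_fst_peaks(self.windows(fsts), max_gap_windows=1)
        assert len(peaks) == 1
        assert peaks["n_windows"].iloc[0] == 4

    def test_planted_divergence_block_found_as_single_peak(self):
        from lineagescan import PlantedFeature

        block = PlantedFeature(
            "divergence_block", "LG01", 30_000_001, 33_000_000,
            params={"odd_freq": 0.98, "even_freq": 0.43, "n_snps": 300},
        )
        sim = simulate_cohort(
            SimulationConfig(seed=61, n_variants=5000, target_fst=0.02, planted_blocks=[block])
        )
        w = window_stats(sim.gm, sim.metadata["lineage"], window_bp=100_000)
        peaks = detect_fst_peaks(w, fst_threshold=0.25)
        overlapping = peaks[(peaks["end"] > 30_000_000) & (peaks["start"] < 33_000_000)]
        assert len(peaks) == 1 and len(overlapping) == 1


class TestPopulationSummary:
    def test_monomorphic_population(self):
        dosage = np.array([[0, 2], [0, 2], [1, 0], [1, 0]], dtype=np.int8)
        out = population_summary(make_gm(dosage), ["a", "a", "b", "b"])
        assert out.loc["a", "pct_polymorphic"] == 0
        assert out.loc["a", "pi"] == 0

    def test_private_allele_counting(self):
        # variant 0: alt only in pop a -> private alt for a
        dosage = np.array([[1, 1], [0, 1], [0, 1], [0, 1]], dtype=np.int8)
        out = population_summary(make_gm(dosage), ["a", "a", "b", "b"])
        assert out.loc["a", "private_alleles"] == 1
        assert out.loc["b", "private_alleles"] == 0

    def test_fis_near_zero_under_hwe(self):
        sim = simulate_cohort(SimulationConfig(seed=67, n_odd=30, n_even=30,
                                               n_variants=10_000, target_fst=0.0))
        out = population_summary(sim.gm, sim.metadata["lineage"])
        assert abs(out.loc["odd", "fis"]) < 0.03
        assert abs(out.loc["even", "fis"]) < 0.03

    def test_label_length_mismatch_rejected(self):
        gm = make_gm(np.zeros((2, 3), dtype=np.int8))
        with pytest.raises(ValueError):
            pop_indices(gm, ["a", "a", "b"])
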