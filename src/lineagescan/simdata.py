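"""Synthetic two-lineage cohorts with planted genomic features.

The generator emulates a pair of reproductively isolated year-class
lineages (odd/even broodlines) of a diploid species. Background
divergence follows the Balding-Nichols model: for each variant an
ancestral frequency ``p0`` is drawn, and each lineage's frequency is
drawn from ``Beta(p0 (1-F)/F, (1-p0)(1-F)/F)``, which has mean ``p0``
and variance ``F p0 (1-p0)`` — so the genome-wide Hudson Fst between
the lineages converges to the single divergence parameter ``F``.

On top of the background the generator can plant:

* ``divergence_block`` / ``selection_locus`` — a region whose variants
  take fixed lineage frequencies (e.g. the centromeric high-Fst blocks).
* ``deletion_haploblock`` — a region inherited as a single locus: each
  sample draws one AA/AB/BB state per lineage-specific haplotype
  frequency and every variant in the block reports that state (plus a
  small genotype-error rate).
* ``sex_locus`` — an X/Y-like region where males are heterozygous and
  females homozygous reference, with designated sdY marker sites whose
  read depth scales with sdY copy number.

Allele-balance artifacts (variants whose heterozygous reads are drawn
with minor-allele probability 0.12, below the 20% filtering rule) and
local LD blocks (variants within a block share one latent frequency
draw plus jitter) complete the features the downstream filters and
scans are designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix
from .vcfio import write_vcf

__all__ = [
    "PlantedFeature",
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_depths",
    "simulate_mito",
    "write_cohort",
    "write_fasta",
]

_RIVERS = ("Atnarko", "Kitimat", "Quinsam", "Snootli", "Deena", "Yakoun")
_AB_ARTIFACT_MINOR_PROB = 0.12  # below the 0.20 allele-balance rule


@dataclass
class PlantedFeature:
    """A genomic feature injected into the simulated cohort.

    ``start``/``end`` are 1-based inclusive bp. ``params`` depend on
    ``kind``: divergence/selection blocks take ``odd_freq``/``even_freq``
    (alt-allele frequencies per lineage); deletion haploblocks take
    ``odd_freq``/``even_freq`` (alt-haplotype frequencies) and optional
    ``genotype_error``; sex loci take optional ``n_sdy_sites`` and
    ``error``. Any kind accepts ``n_snps`` to inject that many evenly
    spaced variants into the region (guaranteeing marker density).
    """

    kind: str
    chrom: str
    start: int
    end: int
    params: dict = field(default_factory=dict)

    _KINDS = {"divergence_block", "deletion_haploblock", "sex_locus", "selection_locus"}

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.start > self.end:
            raise ValueError("feature start must be <= end")
        for key in ("odd_freq", "even_freq"):
            if key in self.params and not 0 <= self.params[key] <= 1:
                raise ValueError(f"{key} must be in [0, 1]")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study design this package targets: 31 odd-year
    and 30 even-year diploids, mean sequencing depth 30x, and a
    between-lineage divergence of F = 0.2 under Balding-Nichols.
    ``ld_block_size = 0`` disables LD (independent variants).
    """

    seed: int = 0
    n_odd: int = 31
    n_even: int = 30
    n_variants: int = 20_000
    chrom: str = "LG01"
    chrom_length: int = 60_000_000
    target_fst: float = 0.2
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    planted_blocks: list[PlantedFeature] = field(default_factory=list)
    mean_depth: float = 30.0
    ab_artifact_fraction: float = 0.0
    ld_block_size: int = 0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_odd + self.n_even <= 0:
            raise ValueError("cohort must contain at least one sample")
        if not 0 <= self.target_fst < 1:
            raise ValueError("target_fst must be in [0, 1); F = 1 is degenerate")
        lo, hi = self.ancestral_maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("ancestral_maf_range must be within (0, 0.5]")
        for prop in (self.ab_artifact_fraction, self.missing_rate):
            if not 0 <= prop <= 1:
                raise ValueError("proportions must be in [0, 1]")
        by_kind: dict[str, list[PlantedFeature]] = {}
        for f in self.planted_blocks:
            for other in by_kind.get(f.kind, []):
                if f.chrom == other.chrom and f.start <= other.end and other.start <= f.end:
                    raise ValueError(f"overlapping planted blocks of kind {f.kind!r}")
            by_kind.setdefault(f.kind, []).append(f)


@dataclass
class SimulatedCohort:
    """Everything the simulator produced, including ground truth."""

    gm: GenotypeMatrix
    metadata: pd.DataFrame  # sample_id, lineage, river, sex
    features: pd.DataFrame  # planted-feature table (kind, chrom, start, end, params)
    block_truth: pd.DataFrame  # per-sample haploblock states (sample_id, feature, state)
    artifact_positions: np.ndarray  # positions of allele-balance artifact variants
    sdy_sites: np.ndarray  # positions of sdY marker sites (empty if no sex_locus)
    lineage_freqs: pd.DataFrame  # per-variant true odd/even alt frequencies


def _balding_nichols(rng: np.random.Generator, p0: np.ndarray, fst: float) -> np.ndarray:
    if fst == 0:
        return p0.copy()
    scale = (1.0 - fst) / fst
    return rng.beta(p0 * scale, (1.0 - p0) * scale)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw a full cohort: genotypes, depths, allele depths, metadata, truth.

    The same seed reproduces the output exactly.
    """
    rng = np.random.default_rng(config.seed)
    n_odd, n_even = config.n_odd, config.n_even
    n_samples = n_odd + n_even

    # -- sample metadata ------------------------------------------------
    sample_ids = [f"odd_{i:03d}" for i in range(n_odd)] + [
        f"even_{i:03d}" for i in range(n_even)
    ]
    lineage = np.array(["odd"] * n_odd + ["even"] * n_even)
    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "lineage": lineage,
            "river": [_RIVERS[i % len(_RIVERS)] for i in range(n_samples)],
            "sex": ["M" if i % 2 == 0 else "F" for i in range(n_samples)],
        }
    )
    is_male = (metadata["sex"] == "M").to_numpy()

    # -- variant positions ---------------------------------------------
    positions = np.sort(
        rng.choice(np.arange(1, config.chrom_length + 1), size=config.n_variants, replace=False)
    )
    for feat in config.planted_blocks:
        n_extra = int(feat.params.get("n_snps", 0))
        if n_extra:
            extra = np.linspace(feat.start, feat.end, n_extra).astype(np.int64)
            positions = np.union1d(positions, extra)
    m = len(positions)

    # -- background lineage frequencies (Balding-Nichols, optional LD) --
    lo, hi = config.ancestral_maf_range
    if config.ld_block_size > 0:
        block_id = positions // config.ld_block_size
        blocks, inverse = np.unique(block_id, return_inverse=True)
        p0_block = rng.uniform(lo, hi, size=len(blocks))
        odd_block = _balding_nichols(rng, p0_block, config.target_fst)
        even_block = _balding_nichols(rng, p0_block, config.target_fst)
        jitter = rng.normal(0.0, 0.02, size=(2, m))
        p_odd = np.clip(odd_block[inverse] + jitter[0], 0.01, 0.99)
        p_even = np.clip(even_block[inverse] + jitter[1], 0.01, 0.99)
        p0 = p0_block[inverse]
    else:
        p0 = rng.uniform(lo, hi, size=m)
        p_odd = _balding_nichols(rng, p0, config.target_fst)
        p_even = _balding_nichols(rng, p0, config.target_fst)

    # -- planted frequency overrides ------------------------------------
    in_feature = np.zeros(m, dtype=bool)
    for feat in config.planted_blocks:
        mask = (positions >= feat.start) & (positions <= feat.end)
        in_feature |= mask
        if feat.kind in ("divergence_block", "selection_locus"):
            p_odd[mask] = feat.params.get("odd_freq", p_odd[mask])
            p_even[mask] = feat.params.get("even_freq", p_even[mask])

    # -- genotypes ------------------------------------------------------
    dosage = np.empty((n_samples, m), dtype=np.int8)
    dosage[:n_odd] = rng.binomial(2, p_odd, size=(n_odd, m))
    dosage[n_odd:] = rng.binomial(2, p_even, size=(n_even, m))

    # -- haploblock and sex-locus overrides -----------------------------
    block_truth_rows = []
    sdy_sites = np.empty(0, dtype=np.int64)
    for fi, feat in enumerate(config.planted_blocks):
        mask = (positions >= feat.start) & (positions <= feat.end)
        if feat.kind == "deletion_haploblock":
            err = feat.params.get("genotype_error", 0.01)
            freq = np.where(
                lineage == "odd", feat.params.get("odd_freq", 0.5), feat.params.get("even_freq", 1.0)
            ).astype(float)
            state = rng.binomial(2, freq)  # per-sample count of alt haplotypes
            dosage[:, mask] = state[:, None]
            if err > 0:
                flips = rng.random((n_samples, int(mask.sum()))) < err
                dosage[:, mask] = np.where(
                    flips, rng.integers(0, 3, size=(n_samples, int(mask.sum()))), dosage[:, mask]
                ).astype(np.int8)
            for s, st in zip(sample_ids, state):
                block_truth_rows.append((s, f"feature_{fi}", ("AA", "AB", "BB")[st]))
        elif feat.kind == "sex_locus":
            err = feat.params.get("error", 0.02)
            sexed = np.where(is_male, 1, 0)[:, None] * np.ones(int(mask.sum()), dtype=int)
            flips = rng.random(sexed.shape) < err
            sexed = np.where(flips, rng.integers(0, 3, size=sexed.shape), sexed)
            dosage[:, mask] = sexed.astype(np.int8)
            n_sdy = int(feat.params.get("n_sdy_sites", 4))
            pos_in = positions[mask]
            if len(pos_in) >= n_sdy:
                take = np.linspace(0, len(pos_in) - 1, n_sdy).astype(int)
                sdy_sites = pos_in[take]

    # -- read depths and allele depths ----------------------------------
    depth = rng.poisson(config.mean_depth, size=(n_samples, m)).astype(np.int32)
    het = dosage == 1
    # clean het calls sample both alleles evenly; artifact variants are skewed
    alt_prob = np.full(m, 0.5)
    eligible = np.flatnonzero(~in_feature)
    n_artifacts = int(round(config.ab_artifact_fraction * m))
    artifact_idx = rng.choice(eligible, size=min(n_artifacts, len(eligible)), replace=False)
    alt_prob[artifact_idx] = _AB_ARTIFACT_MINOR_PROB
    alt_reads = rng.binomial(depth, alt_prob[None, :])
    ad = np.zeros((n_samples, m, 2), dtype=np.int32)
    ad[het, 0] = (depth - alt_reads)[het]
    ad[het, 1] = alt_reads[het]
    hom_ref = dosage == 0
    hom_alt = dosage == 2
    ad[hom_ref, 0] = depth[hom_ref]
    ad[hom_alt, 1] = depth[hom_alt]

    # -- missingness ----------------------------------------------------
    if config.missing_rate > 0:
        miss = rng.random((n_samples, m)) < config.missing_rate
        dosage[miss] = MISSING
        ad[miss] = 0
        depth[miss] = 0

    variants = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": positions,
            "ref": "A",
            "alt": "T",
            "n_alt": 1,
            "is_snp": True,
        }
    )
    gm = GenotypeMatrix(
        sample_ids=sample_ids,
        variants=variants,
        dosage=dosage,
        allele_depths=ad,
        depth=depth,
        metadata=metadata,
    )
    features = pd.DataFrame(
        [
            {
                "feature": f"feature_{i}",
                "kind": f.kind,
                "chrom": f.chrom,
                "start": f.start,
                "end": f.end,
                **{f"param_{k}": v for k, v in f.params.items()},
            }
            for i, f in enumerate(config.planted_blocks)
        ]
    )
    return SimulatedCohort(
        gm=gm,
        metadata=metadata,
        features=features,
        block_truth=pd.DataFrame(block_truth_rows, columns=["sample_id", "feature", "state"]),
        artifact_positions=positions[np.sort(artifact_idx)],
        sdy_sites=sdy_sites,
        lineage_freqs=pd.DataFrame({"pos": positions, "p_odd": p_odd, "p_even": p_even}),
    )


def simulate_depths(
    config: SimulationConfig,
    copy_number_per_sample: dict[str, float],
    positions: np.ndarray,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Poisson read depths at ``positions`` for each sample.

    The depth at a position is ``Poisson(mean_depth * multiplier)``
    where the multiplier equals the sample's sdY copy number inside a
    planted ``sex_locus`` region (single-copy baseline) and 1 elsewhere.
    Returns a samples x positions DataFrame (columns are positions).
    """
    if config.mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if any(v < 0 for v in copy_number_per_sample.values()):
        raise ValueError("copy-number multipliers must be nonnegative")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    positions = np.asarray(positions)
    if sample_ids is None:
        sample_ids = list(copy_number_per_sample)
    in_sdy = np.zeros(len(positions), dtype=bool)
    for feat in config.planted_blocks:
        if feat.kind == "sex_locus":
            in_sdy |= (positions >= feat.start) & (positions <= feat.end)
    mult = np.ones((len(sample_ids), len(positions)))
    for i, s in enumerate(sample_ids):
        mult[i, in_sdy] = copy_number_per_sample.get(s, 1.0)
    depths = rng.poisson(config.mean_depth * mult)
    return pd.DataFrame(depths, index=sample_ids, columns=positions)


def simulate_mito(
    n_samples: int,
    length_bp: int,
    haplotype_spec: list[tuple],
    seed: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Aligned mitochondrial sequences with a planted haplotype tree.

    ``haplotype_spec`` entries are ``(hap_id, n_carriers, steps_from_root)``
    or ``(hap_id, n_carriers, steps_from_root, parent_id)``. Without a
    parent, a haplotype mutates ``steps`` globally unique positions of
    the root sequence, so any two parentless haplotypes are
    ``s_a + s_b`` steps apart. With a parent, the haplotype inherits the
    parent's mutations and adds ``steps_from_root - parent_steps`` new
    ones (shared ancestry: it sits that many steps from its parent).

    Returns ``(records, assignment)`` where records are
    ``(sample_id, sequence)`` pairs and the assignment table maps each
    sample to its haplotype.
    """
    rng = np.random.default_rng(seed)
    ids = [entry[0] for entry in haplotype_spec]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate haplotype ids")
    total = sum(entry[1] for entry in haplotype_spec)
    if total != n_samples:
        raise ValueError(f"carrier counts sum to {total}, expected {n_samples}")
    if any(entry[2] > length_bp for entry in haplotype_spec):
        raise ValueError("steps cannot exceed sequence length")

    bases = np.array(list("ACGT"))
    root = rng.integers(0, 4, size=length_bp)
    free = list(rng.permutation(length_bp))  # global pool keeps mutation sets disjoint

    hap_seqs: dict[str, np.ndarray] = {}
    hap_steps: dict[str, int] = {}
    for entry in haplotype_spec:
        hap_id, _, steps = entry[0], entry[1], entry[2]
        parent = entry[3] if len(entry) > 3 else None
        if parent is None:
            base_seq, base_steps = root, 0
        else:
            if parent not in hap_seqs:
                raise ValueError(f"parent {parent!r} must be declared before {hap_id!r}")
            base_seq, base_steps = hap_seqs[parent], hap_steps[parent]
        extra = steps - base_steps
        if extra < 0:
            raise ValueError(f"{hap_id!r}: steps_from_root below its parent's")
        seq = base_seq.copy()
        for _ in range(extra):
            pos = free.pop()
            seq[pos] = (seq[pos] + rng.integers(1, 4)) % 4
        hap_seqs[hap_id] = seq
        hap_steps[hap_id] = steps

    records, rows = [], []
    i = 0
    for entry in haplotype_spec:
        hap_id, n_carriers = entry[0], entry[1]
        seq_str = "".join(bases[hap_seqs[hap_id]])
        for _ in range(n_carriers):
            sid = f"mito_{i:03d}"
            records.append((sid, seq_str))
            rows.append((sid, hap_id))
            i += 1
    return records, pd.DataFrame(rows, columns=["sample_id", "haplotype"])


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_cohort(sim: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write VCF, sample metadata TSV and planted-feature truth tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "metadata": out / "samples.tsv",
        "features": out / "planted_features.tsv",
        "block_truth": out / "haploblock_truth.tsv",
    }
    write_vcf(sim.gm, paths["vcf"])
    sim.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    sim.features.to_csv(paths["features"], sep="\t", index=False)
    sim.block_truth.to_csv(paths["block_truth"], sep="\t", index=False)
    return paths
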