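# Methods

`lineagescan` analyses whole-genome resequencing genotypes from two
reproductively isolated lineages of a species with a strict two-year
life cycle — odd-year and even-year broodlines that spawn in the same
rivers but never interbreed. This note records the models, estimators,
parameter choices and numerical conventions the package uses, and what
its synthetic cohorts can and cannot establish about real data.

## The synthetic cohort

Real study cohorts of this design are ~30 diploids per lineage
sequenced to ~30x; the generator's defaults mirror that (31 odd-year +
30 even-year samples, mean depth 30, one 60-Mbp chromosome).

**Divergence model.** Background allele-frequency divergence follows
the Balding–Nichols model: per variant an ancestral frequency `p0` is
drawn uniformly from the configured minor-allele band (default
0.05–0.5), and each lineage draws its own frequency from
`Beta(p0(1−F)/F, (1−p0)(1−F)/F)`. This Beta has mean `p0` and variance
`F·p0(1−p0)`, so the genome-wide Hudson Fst between lineages converges
to `F` — a single dial that maps directly onto the statistic the
pipeline estimates. `F = 1` is rejected (degenerate Beta). The model is
exchangeable across loci and has no demographic history; it is a
calibration target, not a coalescent simulation.

**Linkage disequilibrium** is emulated, not simulated: variants within
a block of configurable physical size copy one shared latent frequency
draw per lineage plus N(0, 0.02) jitter. This produces the high local
r² the LD-thinning contract needs; it does not reproduce realistic LD
decay curves.

**Planted features** override the background inside their intervals:
divergence/selection blocks impose fixed per-lineage frequencies;
deletion haploblocks draw one AA/AB/BB state per sample from
`Binomial(2, lineage frequency)` and copy it to every site in the block
with a small genotype-error rate (default 1%); sex loci make males
heterozygous and females homozygous-reference (an X/Y-like signature)
and designate sdY marker sites whose Poisson depth scales with the
sample's copy number. Allele-balance artifacts draw heterozygous read
counts with minor-allele probability 0.12 — deliberately below the 20%
filter rule, so the filter has planted true positives.

**What passing tests show.** Parameter recovery and planted-feature
detection on these cohorts demonstrate that the estimators implement
their definitions and behave correctly under the stated models. They do
not demonstrate robustness to real-data pathologies the generator omits:
reference bias, batch effects in depth, indel-adjacent miscalls,
population substructure within a lineage, or realistic recombination.

## Filtering

Three stages, in the order a practitioner would run them:

1. **Hard filters** — biallelic SNPs only, MAF ≥ 0.05 (boundary
   inclusive), call rate ≥ 0.9. MAF is computed over called alleles.
2. **Allele balance** — per variant, ref and alt reads are pooled over
   heterozygous calls only; the record is dropped when
   `min(sum)/max(sum) < 0.20` (strict inequality keeps the exact-0.20
   case). Pooling across samples, rather than testing each het call,
   treats the rule as the per-variant filter it is; sites with no het
   call, or no usable AD, are kept (the latter flagged `untestable`).
3. **LD thinning** — greedy left-to-right per chromosome: drop a
   candidate whose r² with any kept variant within 20 kbp exceeds 0.4,
   or when 2 kept variants already sit within the window. r² is the
   squared genotype correlation over samples called at both sites;
   monomorphic pairs count as r² = 0. The retained set of any given
   thinning dialect is tool-specific; downstream statistics only need
   "low mutual LD", which this contract guarantees deterministically.

All three stages are idempotent, which the tests assert.

## Windowed statistics

Windows are non-overlapping 10-kbp tiles by default (0-based half-open,
BED-compatible); a step parameter allows sliding windows.

* **Fst** — Hudson's estimator, combined per window as a ratio of sums:
  per site `num = (p̂1−p̂2)² − p̂1(1−p̂1)/(n1−1) − p̂2(1−p̂2)/(n2−1)`,
  `den = p̂1(1−p̂2) + p̂2(1−p̂1)` with `n` the called allele counts.
  Ratio-of-averages is the stable choice for window scans; single-site
  Fst can be negative (sampling correction), window Fst is ≤ 1 with
  equality iff every used site is a fixed difference.
* **pi / dxy** — per-site `2p̂(1−p̂)·n/(n−1)` and
  `p̂1(1−p̂2)+p̂2(1−p̂1)`, summed and divided by the window length in
  bp; monomorphic positions contribute zero, the window length
  denominates.
* **Tajima's D** — the 1989 normalization with each diploid contributing
  two sequences. With per-site missingness the pairwise-diversity term
  uses each site's own called count; the normalization constants need a
  single `n`, for which the rounded mean called count over segregating
  sites is used (sites here have near-uniform call rates, so the choice
  is immaterial to several decimals). NA when S = 0 or n < 4.
* **Fst peaks** — consecutive windows with Fst > 0.25 merge into peaks,
  tolerating one below-threshold window inside a peak; peaks report bp
  extent, member count, mean/max Fst and whether the max exceeds the
  0.5 highlight level.

Different published Fst estimators (Weir–Cockerham, Nei variants)
differ numerically on the same data; exact reproduction of any
particular tool's window track is not claimed.

## Individual metrics

Shared-allele percent between two diploids averages
`(2 − |d_i − d_j|)/2` over sites called in both (the denominator counts
only co-called sites; missing handling is otherwise undefined in common
usage). IBS dissimilarity is defined as its complement, `1 − IBS`; only
the ordering it induces is consumed by the clustering, so the simpler
form replaces the more elaborate weighting some packages apply.
Clustering is scipy average-linkage agglomeration; rows are passed in
sample-id order so ties resolve reproducibly. The heterozygosity ratio
is `n_het / n_hom_alt` (NA when the sample has no hom-alt call) and
het/kbp divides the het count by a fixed assembly length
(2,528,518,120 bp by default) times 1000.

## EigenGWAS

The GRM is `ZZᵀ/m` over standardized dosages
`z = (d − 2p̂)/√(2p̂(1−p̂))` with missing dosages mean-imputed (z = 0);
monomorphic columns are excluded. Under HWE the expected diagonal is 1,
which the tests check. Eigenvectors take the sign making their
largest-magnitude element positive. The scanned axis defaults to EV1 —
in a two-lineage cohort it separates the lineages — and any externally
computed structure axis (e.g. a discriminant axis) can be supplied
instead.

Per SNP, ordinary least squares of the axis on dosage over called
samples. The Wald statistic uses the MLE residual variance (RSS/n), so
`chi2 = n·r²/(1−r²)` holds as an exact identity. The genomic inflation
factor is `median(chi2)/0.4549` (the χ²₁ median); drift between
diverged populations inflates every marker's statistic roughly
uniformly, and dividing by λGC re-centres the genome-wide distribution
so that only loci standing above the drift background stay significant.

**P-value null.** `n·r²/(1−r²)` equals `n/(n−2)` times an F(1, n−2)
variable under the null. At cohort-scale n (30–60) the χ²₁ limit is
anti-conservative in the far tail — badly enough that a Bonferroni
threshold at m = 5,000 markers produces family-wise false positives in
over half of null scans. P-values are therefore computed from the exact
scaled-F null; the statistic, its algebraic identity, and the λGC
definition are unchanged, and family-wise error control (checked over
50 null replicates) holds.

Significant SNPs (p_gc below α/m, α = 0.05) chain into peaks while
consecutive gaps stay ≤ 100 kbp; chains need ≥ 5 SNPs (true selected
loci drag linked neighbours to significance; lone significant markers
are more often alignment artifacts). The lead SNP has the lowest
corrected p-value, ties to the lowest position.

## Haploblocks and Hardy–Weinberg

A sample's AA/AB/BB call over a region uses its fraction of
heterozygous and homozygous called sites: AB when het ≥ 0.5, else
AA/BB when the corresponding homozygous fraction ≥ 0.8, else NA; at
least 50 called sites are required. The thresholds codify what a
curator does when sorting an IGV genotype raster by eye, and are
exposed as parameters.

The block allele frequency is `p = (2·nAA + nAB)/2n` and the HWE test
is a chi-square goodness-of-fit against `(np², 2np(1−p), n(1−p)²)`.
The default charges **2 degrees of freedom** (three classes against a
fully specified expectation), the convention under which the pooled
odd-year counts (8, 15, 8) give p = 0.984; since p̂ is estimated from
the same counts, the statistic's true asymptotic null is χ²₁ and the
df = 2 p-values are conservative — the df = 1 convention is available
via a flag, and the tests verify df = 1 p-values are uniform on
simulated equilibrium blocks while df = 2 ones are stochastically
larger.

## Mitochondrial networks

Sequences identical at all mutually unambiguous positions collapse into
one haplotype; step distances are Hamming counts with positions
excluded pairwise when either base is ambiguous or a gap (a position
unreadable in one sample should not count as a difference). The network
is a minimum spanning tree (Kruskal over the complete step-distance
graph, edges sorted by weight then lexicographic id pair, so ties
resolve deterministically); no median vectors are inferred — with few,
well-separated haplotypes the MST conveys the same structure as a
median-joining network without inventing unobserved nodes. Mutation
frequency is steps/length × 100, reported at full precision and rounded
to one significant figure. Sharing analysis lists haplotypes whose
carriers span more than one group and, per group pair, the minimum step
distance between group-private haplotypes.

Sequences may come from an aligned FASTA or be reconstructed from the
mitochondrial contig of the variant file (haploid logic: alt base when
dosage ≥ 1, N when missing).

## sdY and sex

Copy number is `mean(depth at the four sdY marker sites)/mean(depth at
all retained variants)` — variant-site depth, not genome-position
depth, mirrors how the denominator is obtained in practice. A ratio
≥ 1.5 flags a multi-copy sample; the integer copy estimate (ratio
rounded) is display-only because the mapping of intermediate ratios to
copies is not identifiable from depth alone. The two sdY haplotypes
(CGGA/TTAC at the four non-coding sites) are typed only from fully
concordant homozygous calls with ≥ 3 sites called; anything else is
`mixed`/NA. Runs of het/homozygosity near the sex locus use 25-site
windows labelled het-run (het fraction ≥ 0.6) or hom-run (≤ 0.1).

The sex-association scan is an allelic 2×2 chi-square with continuity
correction, switching to Fisher's exact test when any expected cell is
below 5. It replaces a logistic-regression-plus-permutation GWA: with a
balanced design, a binary trait and no covariates the two target the
same allelic association, and the exact test needs no permutation
machinery.

## Problem sizes

Tests and the acceptance script run on cohorts of 30–61 diploids and
1,000–50,000 variants — sizes at which every estimator's asymptotic
behaviour is already visible and a full run completes in minutes on one
CPU. Null calibration uses 50 replicate scans at 5,000 markers;
estimator-recovery checks use 50,000 independent markers.

## Known limitations

* The generator's LD and demography are stylized (see above); absolute
  values of pi/dxy/Tajima's D on real data depend on mutation and
  recombination processes the simulation does not model.
* The LD-thinning retained set is contract-defined, not a bit-match to
  any external pruning tool.
* Haploblock calling assumes the block behaves as a single locus across
  its whole interval; recombinant or mosaic samples will fall into the
  ambiguous (NA) class.
* The copy-number estimator assumes depth scales linearly with copy
  number and that the marker sites map uniquely; collapsed paralogs
  violate both.
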