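# Methods

## Input model and conventions

The pipeline starts from Popoolation2 `sync` count tables (scaffold,
position, reference base, then one `A:T:C:G:N:del` sextuple per pool) plus a
pool manifest giving each pool's lineage, life history (anadromous or
freshwater) and number of diploid individuals; the haploid pool size is
fixed at 2 × individuals, the standard convention for diploids. All
coordinates are 1-based inclusive internally (sync/GFF convention); BED
output converts to 0-based half-open at write time only. `N` and `del`
counts contribute to coverage but never to allele calls.

Upstream read processing (trimming, mapping, base-quality filtering,
variant discovery) is out of scope: the pipeline consumes counts. The
caller-level quality filters that cannot be recomputed from counts are
represented only by the count-level rules below — a deliberate reduction.

## SNP calling

Per lineage, a site is retained iff (a) exactly two of A/T/C/G have nonzero
counts summed over the lineage's pools, (b) the pooled minor-allele count is
≥ 4, and (c) every pool's coverage lies in [10, 2 × that pool's genome-wide
mean], the mean being computed from all input sites before any filtering.
Biallelic status and the minor allele are decided from lineage-pooled
counts because variants are called per lineage; ties in pooled counts are
broken deterministically (the |ΔAF| statistic is invariant to the labels).
The per-pool frequency is minor/(minor+major) reads; a site where some pool
has zero major+minor reads (possible only when its coverage is all N/del)
is dropped because the frequency is undefined there. SNPs within 10 bp of a
supplied indel position (inclusive) are removed. The coverage and
minor-count filters commute; tests assert this.

## Standardized ΔAF scan

For every SNP and every (anadromous, freshwater) pool pair within a
lineage, the raw statistic is d = |f_fresh − f_anad|, the absolute
frequency difference (allele labels are arbitrary across populations, and
outlier logic is one-sided on magnitude). Each pair is standardized against
its own genome-wide mean and population (divide-by-n) standard deviation,
z = (d − μ)/σ, before averaging over pairs; per-pair scaling removes
pair-specific drift baselines and is the default. A pooled alternative
(single μ/σ over all pairs' values) is available behind
`ScanParams(pooled_standardization=True)`; defaults are unchanged. With
~10⁵ SNPs the divide-by-n vs divide-by-(n−1) distinction is negligible, but
it must be fixed for reproducibility. SNPs monomorphic within a pair
contribute d = 0 and stay in the μ/σ computation — they are lineage SNPs by
construction.

Windows are 20 consecutive SNPs, advanced every 10 SNPs along each
scaffold; only full windows count, and only the 1000 longest scaffolds
(ties broken by name) are scanned, mirroring the practice of excluding
small repeat-rich scaffolds. The window statistic is the mean over the
window of the per-SNP mean z.

## Permutation null and thresholds

Each permutation reassigns pools to the anadromous/freshwater labels
uniformly at random among assignments preserving the observed group sizes
(the statistic is defined over anadromous × freshwater pairs, so group
sizes must be fixed for exchangeability; the identity assignment is
allowed — with few pools the distinct assignments are exhausted anyway) and
reruns the whole scan with the window-grid offset drawn uniformly from
{1..20}, so every possible 20-SNP window phase is sampled. Window
statistics from all permutations (default 1000) are pooled into one
empirical null per lineage; thresholds are genome-wide nearest-rank 99th
and 99.9th percentiles of that pooled distribution, with ties at the
threshold included (≥). Per-window p-values are add-one empirical
p = (1 + #{null ≥ stat})/(1 + #null), computed against the pooled null.

Implementation note: a pool pair's standardized column does not depend on
the labels, so per-pair columns are cached once and each permutation only
selects and averages columns — numerically identical to a full rerun
(asserted in tests). The master seed spawns one independent stream per
permutation index, so results do not depend on execution order.

## Regions, annotation, parallelism

Outlier windows on a scaffold merge transitively when separated by ≤
20 000 intervening bases (or overlapping); the region span is the union
hull, and the region's peak statistic is its best window. Genes are
attached when their span intersects the region extended by 20 kb on both
sides; the flank applies to annotation only, never to region-overlap tests.
Note the two rules' boundaries differ by construction: a 20 000-base
separation still merges two windows, while a gene starting 20 000 bases
past a region end no longer intersects the extended span.

Sharing between two region sets counts a region as shared when it
intersects (≥ 1 bp) any region of the other set, and reports
100 × mean(shared_A/|A|, shared_B/|B|) — symmetric, and robust to the two
sets having different sizes. "Complete parallelism" loci are maximal
intervals covered by a region in every set considered. Interval overlap on
the common reference was chosen over any distance threshold as the simplest
operational definition of "the same region". Shared polymorphism between
lineages matches sites by (scaffold, position) — a polymorphic site being
any called SNP that is variable, or fixed for a non-reference allele, in at
least one pool — and averages the two directional percentages the same way.

Per-population outlier scans (used for within-lineage parallelism) restrict
the pipeline to the lineage's anadromous pools plus one freshwater
population at the 99th percentile; with a single freshwater pool this is
exactly the lineage scan.

## Population genetics

Statistics are computed over the same 20-SNP windows as the scan so
outlier/background contrasts align 1:1 with scan windows, and they are
averages over the window's variant sites (monomorphic sites between SNPs
are not included), not per-bp — stated in output headers. Per site,
π̂ = C/(C−1) × (1 − Σp̂ᵢ²) with read frequencies p̂ᵢ and allele coverage C
(unbiased for the pool's heterozygosity under binomial read sampling;
undefined below C = 2). D_XY = p₁(1−p₂) + p₂(1−p₁) for the same allele's
frequencies in two pools, averaged over all anadromous × freshwater pairs.
Tajima's D uses the standard a₁…e₂ constants with the window's effective
sample size n: per site n_eff = min(coverage, haploid pool size), since
reads cannot sample more chromosomes than the pool holds, and per window
n = ⌊mean n_eff⌋; S counts sites segregating in the pool and θ_W = S/a₁.
These are standard pool-seq approximations, not the exact pool-size-
corrected estimators of Popoolation — read sampling misses rare alleles,
which biases S (and hence D) at low coverage; the neutral-calibration test
therefore runs at high coverage, and empirical D on Beta-distributed
simulated frequencies should not be read as a demographic signal. Undefined
values (S = 0, n < 4, C < 2) are NaN, never zero. Outlier vs background
contrasts report group means and a two-sided Mann–Whitney U p-value; the
significance test was an open choice and U is the default for its lack of
distributional assumptions.

## Convergence

Heat maps: for each 99.9th-percentile window span of a target lineage, each
lineage's cell is the mean per-SNP z over its SNPs in that span; cells
backed by fewer than two SNPs are excluded (`NA:lt2snps`), since a one-SNP
mean is not a window statistic. The target's own column reproduces the scan
statistics. The shared-nonsynonymous test takes sites nonsynonymous in both
lineages (matched by position only — effect tables carry no allele phase),
and counts those whose per-site mean z is ≥ the 95th nearest-rank
percentile of mean z over *all* of each lineage's nonsynonymous sites, in
both lineages. Using the standardized, pair-averaged z as "per-site ΔAF"
keeps the test consistent with the scan; the reference distribution is
per-lineage all-nonsynonymous sites (not just shared ones).

## Synthetic data

The generator emulates the structure the pipeline assumes: 2–4 lineages ×
2–6 pools, scaffolded genomes, per-lineage SNP sets with a configurable
fraction of positions shared by all lineages, ancestral frequencies from
Beta(0.7, 0.7) (a mildly U-shaped spectrum; near-fixed sites are then
removed by the minor-count filter, as in real data), per-pool drift as
Normal(0, 0.5) noise on the logit scale (keeping frequencies inside (0,1)
without boundary pileups), coverage ~ Poisson(32) per pool and site, and
alternative-allele reads ~ Binomial(coverage, frequency). Defaults mirror
the targeted study design — four lineages with (2,3), (2,3), (2,1), (2,1)
anadromous/freshwater pools of 25 diploids at a 32× mean coverage — and are
not tuned per experiment; validation experiments state their own sizes
explicitly.

Planted selection shifts every freshwater pool of a lineage (optionally a
subset, for partial-parallelism scenarios) so the pre-drift |ΔAF| equals a
target delta, choosing the direction that keeps the target in [0,1] and
clipping with a warning when delta exceeds both headrooms. A
`min_snps_per_region` option tops up SNP positions inside planted regions
so recoverability is guaranteed by construction when an experiment requires
it. Effect classes are drawn per position at fixed rates (3%
nonsynonymous), with an option to force planted sites nonsynonymous as a
positive control for the convergence test. What the simulator does *not*
model: linkage disequilibrium beyond region-level correlation, sequencing
error, coalescent site-frequency spectra, or gene flow — so passing tests
demonstrate the statistics and their calibration, not realism of any
demographic inference on real data.

## Validation experiments and sizes

Null calibration uses 2 lineages × (2+2) pools, 50 000 SNPs at 32×, 200
permutations and 5 seeds (≈ 44 000 windows pooled): observed outlier rates
fall within 3 binomial standard errors of the nominal 1% and 0.1%.
Planted-region recovery uses one (2+3)-pool lineage, 100 000 SNPs and 10
regions of |ΔAF| 0.7 with ≥ 40 SNPs each: on average ≥ 9/10 regions are
recovered at the 99.9th percentile with ≤ 2 false positives. These sizes
keep each experiment under a minute or two while leaving the Monte-Carlo
error well below the tolerances tested. Oracle tests compare the
vectorized window statistics, π and D_XY against loop-based brute-force
reimplementation to 1e-12.

## Numerical and degenerate-input choices

Nearest-rank percentiles use k = ⌈p·N/100⌉ with a 1e-9 guard against
floating-point boundary drift. Zero genome-wide variance of a pair's |ΔAF|
is a hard error naming the pair (standardization undefined). Scaffolds with
fewer than 20 SNPs simply contribute no windows. Empty region sets warn and
yield 0% sharing; empty polymorphic-site sets are errors. All stochastic
stages derive independent streams from one master seed (per permutation
index, and per stage label in the CLI), making every output byte-identical
across reruns and independent of execution order.
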