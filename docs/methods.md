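# Methods

## Scope and model

`poolscan` implements a two-variable genome scan for selection signatures in
a focal population sequenced as a pool, against a panel of related species
sequenced as individuals. The two variables are the pooled minor-allele
frequency (within-population diversity) and the among-species Weir–Cockerham
F_ST (differentiation), both aggregated over sliding genomic windows. A
selective sweep in the focal population depresses local diversity while
increasing differentiation; balancing selection does the opposite. Because
the statistics are dependent in a way that is hard to model parametrically,
candidates are defined empirically, from the joint quantile tails of the two
genome-wide window distributions.

## Site-level estimators

**Pooled MAF.** At a site with per-allele read counts, depth *d* = Σ counts,
major count *m* = max, the estimate is (*d* − *m*)/*d* — equivalently the
summed frequency of all non-major alleles, which handles the occasional
triallelic pileup without dropping the site. Filters: *d* ≥ 15 (`min_depth`)
and ≥ 2 non-major reads (`min_variant_reads`); a single non-major read is
indistinguishable from sequencing error at typical error rates and pool
depths. Sites failing a filter carry an explicit status
(`low_depth` / `singleton_variant` / `monomorphic`) instead of an estimate.
Major-allele ties break toward the lexicographically smallest allele, making
the estimator deterministic; the estimate itself is tie-invariant.

Whether zero-variant (monomorphic) sites belong in the window average is a
genuine convention choice: including them pulls window MAF toward zero
everywhere and compresses the scan's dynamic range. The default excludes
them (`include_monomorphic=False`); the switch exists because either reading
of "average per-site MAF" is defensible, and both paths are tested.

**Variant retention.** Upstream multisample records are reduced to biallelic
SNPs whose quality equals the caller's cap (999 by convention, configurable
— the filter tests equality with the configured maximum rather than
hard-coding the number) and which lie more than 3 bp from any called indel's
anchor position on the same scaffold (|SNP − indel| ≤ 3 removes, the
simplest reading of an indel-proximity exclusion). The record filter is
idempotent and order-checked; a vectorised mask implements the same rule for
the array pipeline and is tested equal to the record-stream version.

**Weir–Cockerham components.** Per site, with r populations of n_i called
diploids, allele frequencies p_i and observed heterozygote frequencies h_i,
the three-component diploid formulation (including the heterozygosity term)
gives a, b, c; θ̂ = a/(a+b+c). Sites where any population has no called
genotype, or where the mean sample size does not exceed one diploid, are
skipped (the individual-level components are undefined). Per-site negative
θ̂ values are retained unclamped so that window sums stay unbiased. The
windowed statistic is the weighted ratio of sums Σa/Σ(a+b+c) over ≥ 100
usable sites (`min_fst_sites`); an unweighted mean-of-ratios variant is
available by flag but is not the default, the weighted form being the
standard headline output of windowed F_ST tools. The implementation is
verified site-by-site against a brute-force allele-copy nested-ANOVA oracle
(sums of squares over the 0/1 allele indicators) at 1e-12.

Pools enter F_ST as one pseudodiploid genotype: both alleles supported by
≥ `min_variant_reads` reads → heterozygote; otherwise homozygous for the
majority allele; below `min_depth` → missing. This understates the pool's
information content but lets a pooled sample represent its species in a
genotype-based estimator.

## Windows

Half-open 0-based windows of 50 kb sliding by 25 kb (defaults), addressed by
start coordinate; trailing windows truncate at scaffold ends. A site
contributes to every window containing it (≤ ⌈size/step⌉). Window MAF needs
≥ 1 estimable site by default — the site minimum is a property of the F_ST
estimate, not of the MAF average — and joint analyses are automatically
restricted to windows with both statistics defined. Fixed differences
(opposite homozygotes between two conspecific individuals) are counted in
non-overlapping 50-kb windows, so per-window counts sum to the genome-wide
total. RPKM and median-scaled window depth are provided as coverage sanity
checks.

## Outlier scan

"Visual outlier" selection is operationalised as a two-threshold rule:

* **membership** — a window joins a candidate run if MAF and F_ST are both
  strictly beyond their `run_tail` (5%) empirical quantiles in the mode's
  directions;
* **confirmation** — a maximal run of ≥ `min_run` (2) consecutive flagged
  windows is reported only if ≥ 1 member is strictly beyond both
  `extreme_tail` (1%) quantiles.

Quantiles are computed genome-wide over the analysed windows with linear
interpolation; strict inequalities mean a degenerate distribution flags
nothing. Runs are defined over the ordered tiling, and a window without
estimates breaks a run — masked or low-coverage stretches should sever
candidate regions rather than bridge them. `min_run` = 2 is the weakest
reading of "consecutive windows" and is configurable. Under independent
uniform statistics the expected extreme-flag rate per mode is
`extreme_tail`², which the calibration test checks at 3 SE.

An identifiability constraint follows from the design: an empirical-tail
procedure can only confirm outliers rarer than its tails, so planted (or
real) signal regions must occupy well under `run_tail` of analysed windows —
and under `extreme_tail` competition for the confirmation step. The
benchmark configuration keeps truth regions at ~2% of windows for this
reason.

## IBS phylogeny

Distances are 1 − mean IBS over pairwise-complete sites (how missing
genotypes entered the original IBS computation is not documented anywhere
authoritative; pairwise-complete is the least wasteful choice and is stated
here as the package's convention). Neighbor joining uses the
Studier–Keppler O(n³) update with deterministic tie-breaking (smallest index
pair) and the exact three-point resolution of the final triple; negative
branch-length estimates are clamped to zero at output only. On additive
matrices the tree inverts the input exactly (tested at 1e-9 on 4- and
6-taxon matrices); an independent cross-check against scikit-bio's NJ runs
in the test suite. Bootstrap support resamples site columns with
replacement, recomputes distance + NJ, and scores each internal bipartition
of the reference tree (unrooted splits, canonicalised against the
lexicographically first leaf).

## Synthetic data

The generator emulates the statistical structure the scan assumes, not a
demographic history:

* **Species frequencies.** Per site, an ancestral frequency uniform on
  (0,1) drifts along the fixed balanced tree ((A,B),(C,D)) — two internal
  and four terminal branches — by independent Gaussian increments with
  variance `species_divergence` · 4p(1−p), truncated to [0,1]. The
  p(1−p) taper is the Wright–Fisher-natural scaling and keeps interior
  frequencies interior; the stated variance applies at p = 0.5. A full
  coalescent would add realism (linkage, shared genealogy) the scan's
  statistics do not require; drift in frequency space is sufficient to
  induce the F_ST structure being measured and keeps the generator a few
  lines of auditable numpy.
* **Pool.** The focal pool is a population of species A: its frequency is
  realised through `pool_chromosomes` (48 = 24 diploids, the pool scale the
  design mirrors) binomial draws, then depth ~ negative-binomial with mean
  `mean_depth` (40, a realistic pool coverage) and variance
  mean + `depth_dispersion`·mean² (0.25; Poisson in the →0 limit), then
  variant reads ~ binomial. Rare alleles can thus be absent from the pool
  entirely, as in real pools.
* **Individuals.** Hardy–Weinberg draws: dosage ~ Binomial(2, p_species),
  two individuals per species by default.
* **Planting.** Sweep regions force the focal population to folded MAF ≤
  `sweep_maf_ceiling` (0.02) and displace the other species by ≥
  `sweep_fst_floor` (0.6) with small jitter; balancing regions pull all
  frequencies to 0.5 ± 0.05. Truth intervals are recorded for scoring.
* **Defaults** (`snp_density` 5e-3/bp, `species_divergence` 0.08) give a
  polymorphism density and background differentiation (window F_ST ~ 0.3)
  typical of congeneric fish comparisons, with 100–300 usable sites per
  50-kb window at the default depth.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure, read-level error, mapping artifacts, indels, coverage
mosaicism, and any demographic history of the focal population (bottlenecks,
admixture). Passing recovery tests therefore demonstrate the scan's
statistical machinery under its own assumptions — clean biallelic sites,
exchangeable windows — not robustness to those real-data complications.

## Benchmark and problem sizes

The standard power evaluation (`benchmark_config`) uses twenty 2-Mb
scaffolds (1,600 windows), five 100-kb sweeps and three 150-kb balancing
regions, ten seeds for recovery and twenty for the null; the phylogeny
check uses ~10⁴ SNPs, 100 bootstrap replicates, twenty seeds; calibration
checks use 10⁴ sites/windows. These sizes give Monte-Carlo standard errors
comfortably inside the asserted tolerances while the full suite runs in
about a minute and a half. The pipeline subsamples sites for the bootstrap
tree (`tree_max_sites`, default 2×10⁴) since IBS distances stabilise well
below typical SNP counts.

## Numerical and degenerate-input choices

Empirical quantiles use numpy's linear interpolation; all flag comparisons
are strict. Window F_ST with a zero component sum is undefined (NaN), as is
per-site θ̂ at monomorphic sites (a = b = c = 0 exactly). All randomness
derives from a single `numpy.random.default_rng(seed)` per run; fixed seed
⇒ byte-identical output files (no timestamps are written). Outputs are
plain text: S5-style window TSV, region BED/TSV, newick with bootstrap
labels, fixed-difference TSV, JSON summary whose every count is
recomputable from the window TSV.

## Known limitations

Pool pseudodiploid coding discards allele-frequency information within the
pool and exaggerates the pool's branch length in the IBS tree. The scan's
thresholds are relative, so it reports the most extreme joint tails even in
a genome with no true signal unless the consecutive-and-extreme rules
filter them (the null benchmark measures exactly this). Quantiles are
genome-wide; per-scaffold heterogeneity in diversity or differentiation
(e.g. sex chromosomes) would need stratified quantiles, which are not
implemented.
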