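# Methods

## Estimators

### π and dXY with invariant sites

Both statistics are ratios of sums over the sites of a window. At one
site, with n₀ REF and n₁ ALT called allele copies in a population
(k = n₀+n₁), the within-population components are

    differences = n₀·n₁,   comparisons = k(k−1)/2,

and between two populations

    differences = n₀ᴬn₁ᴮ + n₁ᴬn₀ᴮ,   comparisons = kᴬ·kᴮ.

A window's π (or dXY) is Σdifferences / Σcomparisons. Invariant sites
contribute zero to the numerator and their full comparison count to the
denominator, which is what makes the estimates per *compared* site
rather than per SNP; a site with missing calls simply contributes fewer
comparisons, so missingness is handled without imputation and without
bias. A window whose comparison count is zero is reported as undefined
(NaN), never as 0. Numerators and denominators are carried in the
output table, so users can re-aggregate across windows (ratio of sums
over any region) rather than averaging window ratios.

### Weir–Cockerham FST

Per biallelic variant site we compute the three variance components of
Weir & Cockerham (1984) for r = 2 populations — a (among populations),
b (among individuals within populations), c (within individuals) — from
the called sample sizes, allele frequencies and observed
heterozygosities. Individuals with any missing allele at a site are
excluded from that site's FST (but their called alleles still count for
π/dXY). A window's FST is Σa / Σ(a+b+c) over its variant sites; the
raw ratio is retained and the reported value is clamped to [0, 1],
matching the convention of setting negative estimates to zero. Sites
where either population has no called individuals, or where the mean
sample size is ≤ 1, are excluded from the sums.

Haploid data (the Y chromosome after haploidization) use the haploid
reduction: allele copies are the sampling units, heterozygosity terms
vanish, and the components reduce to a = (MSP − MSG)/n_c, b = MSG,
c = 0, where MSP and MSG are the among- and within-population mean
squares of the allele indicators. The test suite verifies both forms
against an independent nested-ANOVA derivation to 1e−10. Running a
diploid estimator on haploidized calls would double-count allele
copies; the haploid reduction is the defensible equivalent and is what
this package uses on the Y.

### Bootstrap summaries

Genome-wide means are means over windows with defined values (equal
weighting; the exposed numerators/denominators allow site-weighted
re-aggregation when wanted). Confidence intervals are 95% percentile
bootstrap over 10,000 resamples of windows with replacement; the
half-width (hi−lo)/2 mirrors the "mean ± " presentation of summary
tables. Windows, not sites, are the resampling unit because the
genome-wide quantities summarized are window means and because sites
within a window are not independent.

### PAR partition and the Y:A ratio

X-chromosome windows are assigned to the pseudoautosomal region (PAR)
if their midpoint falls inside the half-open PAR interval; each
partition is summarized separately, since the PAR recombines in both
sexes and carries systematically higher diversity. The Y:autosome
diversity ratio (neutral expectation ¼ under equal sex ratios, since
Y-linked N_e is a quarter of autosomal) is displayed truncated — not
rounded — to two decimals, because truncation is the display convention
the reported values follow; the raw ratio is always returned alongside.

### PBS

Branch lengths use the natural logarithm, T = −ln(1 − FST), the
convention of the PBS literature. Clamping order is fixed and
deliberate: FST is clamped to 0 *before* the transform (a negative
estimate means "no detectable differentiation", i.e. T = 0, not a
negative branch), and PBS = ((T_AB + T_AC) − T_BC)/2 is clamped to 0
*after* the arithmetic. FST = 1 is capped at 1 − 10⁻⁶ so branches stay
finite; `capped_mask` flags affected windows. Outlier calling uses the
empirical quantile with linear interpolation (type 7, numpy's default)
and strict exceedance, so a constant vector yields no outliers. The
quantile is taken over whatever value vector the caller passes —
genome-wide per analysis by default, per chromosome by grouping first.

### CNV FST, VST and cross-validation

Carrier genotypes (ref/het/hom) are coded as diploid allele pairs and
routed through the same per-site Weir–Cockerham components as SNPs, so
the two code paths agree exactly by construction. VST for a locus is
(V_T − V_S)/V_T with V_T the pooled sample variance of copy number
(n−1 denominator, the R `var` convention, as the statistic is
conventionally computed with custom R scripts) and V_S the
population-size-weighted mean within-population variance. VST is
undefined when V_T = 0 or a population has fewer than two called
samples; negative values are reported as-is, since clamping is a
convention only applied to FST and PBS here.

Cross-validation retains a primary call iff a secondary call of the
*same* svtype overlaps it with intersection strictly greater than 50%
of the primary call's length (half-open interval arithmetic; an
intersection of exactly half the length is dropped). The fraction is
measured against the primary call by default because the workflow asks
"which primary calls are supported?", and retention counts are reported
per svtype on the primary set; `reciprocal=True` gives the stricter
symmetric mode. DEL and DUP are analyzed jointly downstream but never
cross-matched in validation; inversions are parsed but excluded from
downstream statistics by default.

### PCA

Variant sites become ALT-dosage columns (0/1/2 diploid, 0/1 haploid);
missing dosages are imputed with the site mean (which is what pushes
high-missingness samples toward the origin, a visible and honest
artifact), columns are centered and scaled by √(p̂(1−p̂)), and samples
are projected on the eigenvectors of the resulting covariance matrix.
Components are sign-oriented so the largest-magnitude loading is
positive, making output deterministic across eigensolvers.

### Model comparison and scaling

AIC = 2k − 2·LL with k the number of optimized parameters; ranking is
ascending AIC with ties broken toward fewer parameters. The scaling
module uses the standard diffusion conventions: θ = 4·N_anc·μ·L anchors
N_anc; population sizes are ν·N_anc; time is in units of 2·N_anc
generations; migration parameters convert as m/(2·N_anc) per
generation. The published two-population fits carry k = 7
(isolation-with-migration: s, ν₁, ν₂, m₁₂, m₂₁, T, misid), k = 4
(strict isolation) and k = 6 (ancient symmetric migration), counts
inferred from the populated parameter cells; the printed IM AIC is
exactly 2k − 2·LL under k = 7, while the other two models' printed AICs
differ by ~0.01 from the printed-precision LL, consistent with rounding.
Likelihood optimization itself is out of scope — the module consumes
fit tables. μ, generation time and callable length are required inputs
with no defaults, because no defensible default exists.

## Synthetic data

The generator exists so that every downstream stage has a ground truth.
Divergence follows Balding–Nichols: ancestral frequency p uniform on
[0.05, 0.95] (keeping MAF filters non-degenerate; no attempt is made to
match an empirical site-frequency spectrum), population frequency
Beta-distributed with mean p and variance F·p(1−p), F = 0 handled as a
point mass. Expected Weir–Cockerham FST between populations simulated
at drift F is close to F, which the suite verifies within ±0.02 at
20+20 diploids and 10,000 sites over 5 seeds. Genotypes are independent
binomial allele draws; a fraction `prop_variant` of sites (default 0.5,
a compromise between realistic sparsity and statistical power at
desk-scale site counts) is polymorphic, the rest emitted as invariant
records; whole genotypes go missing i.i.d. at `missing_rate`.

The X is simulated for females only (diploid) and the Y for males only
(haploid), mirroring how sex chromosomes are analyzed
sex-exclusively; sample counts in `SexChromParams` are per population.
The PAR multiplier scales the polymorphic-site density inside the PAR
interval, which scales expected π linearly while leaving the frequency
distribution unchanged — so a 3.5× multiplier should be recovered as a
3.5× π ratio by the PAR partition, and is (within ±20%).

CNV truth loci are disjoint intervals with per-population carrier
frequencies; per sample, carrier dosage is Binomial(2, q_pop), shared
between both emitted callsets, and copy number is 2 − dosage (DEL) or
2 + dosage (DUP). Both callsets contain every true locus with endpoints
jittered uniformly within ±jitter_bp, plus spurious calls — placed on
CNV-free sequence with lengths resampled from the true calls, so the
length distribution of false calls matches — making up a configurable
fraction of each callset. Differentiated loci (high q in one
population, low in the other) push FST and VST up together, giving the
planted positive FST–VST association.

What the generator does **not** emulate: linkage disequilibrium,
recombination-rate variation, selection, empirical SFS shape,
sequencing-depth-dependent genotype error, or caller-specific biases.
Passing recovery tests therefore demonstrates estimator correctness
under exchangeable-site conditions, not robustness to the correlated
noise structure of real resequencing data.

All randomness flows from one `numpy` Generator seeded per call; no
global state, and identical parameters + seed reproduce outputs
bit-for-bit.

## Numerical and design choices

- Coordinates: 1-based positions in VCFs and on `GenotypeMatrix`;
  0-based half-open everywhere intervals appear (BED, windows, CNVs,
  PAR). Windows tile each chromosome from coordinate 0; terminal
  partial windows are retained and flagged.
- VCF I/O: reading goes through cyvcf2 (handles bgzip, odd headers,
  haploid GTs); writing emits plain VCF v4.2 text with ALT "." for
  invariant records and single-allele GT fields for haploid matrices.
  Round-trip identity is tested for both ploidies.
- Missingness filters run samples-first then sites, a fixed order, so
  the retained site set cannot depend on sample ordering. Sample
  missingness is measured over variant sites only (invariant records in
  real all-sites VCFs often lack calls); site completeness is "fraction
  of samples called ≥ threshold".
- The Y haploidizer sets heterozygous diploid calls to missing rather
  than picking an allele: a het call on a hemizygous chromosome is
  evidence of error, not information. It is idempotent.
- `filter_maf` defaults off; demographic inference needs the full
  frequency spectrum.
- Degenerate inputs yield NaN-marked records (window with no
  comparisons, VST with zero total variance, FST with an uncalled
  population) rather than zeros, and errors only where silent output
  would be meaningless (no samples left, empty male set, fewer than two
  model fits).

## Problem sizes

The test suite and examples run at desk scale: 4,000–25,000 sites,
15–20 diploids per population, 200–500 windows, 60–200 CNV loci,
bootstrap sizes 100–4,000 where the defaults (10,000) would add nothing
to the check. These sizes were chosen so each statistical assertion has
comfortable power at its stated tolerance; all statistics are linear
scans over sites, so production-scale inputs differ only in runtime.

## Known limitations

- FST machinery is two-population (r = 2); the three-population scan is
  built from pairwise tracks, as the PBS construction requires.
- Mixed-ploidy VCFs (diploid + haploid in one file) are not supported;
  sex chromosomes are processed as separate files, which is also the
  analysis convention.
- Multi-allelic records survive reading but only biallelic SNPs pass
  filtering; there is no spanning-deletion or symbolic-allele handling.
- VST accepts any integer copy-number matrix and is agnostic to how the
  copy numbers were derived (caller genotype vs depth ratio).
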