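# divergescan

Population-genomic divergence scans for very recently diverged lineages
(incipient species), built around the analysis style used for sympatric
marine stickleback ecotypes: invariant-site-aware windowed diversity and
differentiation, a three-population selection scan, copy-number-variant
(CNV) differentiation with dual-caller cross-validation,
sex-chromosome-aware processing, and AIC-based demographic model
comparison. Every stage is exercisable on synthetic data with known
ground truth, so the whole pipeline is testable without touching real
sequence data.

## What it computes

**Windowed diversity and differentiation.** Nucleotide diversity π and
absolute divergence d<sub>XY</sub> are ratio-of-sums estimates over 50 kb
windows: per site we accumulate pairwise-difference numerators and
pairwise-comparison denominators (invariant sites included in the
denominator, missing calls simply reducing the comparison count), then
divide the window sums. Relative differentiation uses the Weir &
Cockerham (1984) F<sub>ST</sub> estimator: per-site variance components
*a* (among populations), *b* (among individuals) and *c* (within
individuals), window-aggregated as Σa / Σ(a+b+c), negative estimates
clamped to 0. Haploid data (a haploidized Y chromosome) use the haploid
ANOVA reduction. Genome-wide means get 95% percentile-bootstrap CIs
resampling windows.

**PBS selection scan.** Pairwise windowed F<sub>ST</sub> among a focal
population A, sister B and outgroup C becomes branch lengths
T = −ln(1 − F<sub>ST</sub>), and the Population Branch Statistic
PBS<sub>A</sub> = (T<sub>AB</sub> + T<sub>AC</sub> − T<sub>BC</sub>)/2,
clamped at 0. Windows above the empirical 0.99 quantile are outliers.

**CNV population genetics.** CNVs scored as biallelic carrier loci get
the same Weir–Cockerham F<sub>ST</sub>; integer copy numbers get
V<sub>ST</sub> = (V<sub>T</sub> − V<sub>S</sub>)/V<sub>T</sub>, the
between-population share of copy-number variance. A primary callset is
cross-validated against a second caller by strict >50% length overlap of
same-type calls before outlier scanning and gene-proximity summaries.

**Structure and demography.** Genotype PCA (dosage-scaled covariance
eigendecomposition) and AIC ranking of demographic-model fits
(AIC = 2k − 2·LL), with conversion of diffusion-scaled parameters
(θ, ν, T, m) into natural units.

## Worked example

```python
import divergescan as ds

params = ds.SimulationParams(n_pops=2, n_diploids_per_pop=20,
                             n_sites=20_000, seq_length=2_000_000,
                             divergence_F=0.1, prop_variant=0.2, seed=1)
gm, truth = ds.simulate_split_populations(params)
w = ds.windowed_stats(gm, truth.popmap, "pop1", "pop2", width=50_000)
s = ds.genome_summary(w["fst"].to_numpy(), n_boot=2000, seed=1)
print(f"FST mean {s.mean:.4f}  95% CI [{s.ci_low:.4f}, {s.ci_high:.4f}]")
```

prints

```
FST mean 0.1012  95% CI [0.0965, 0.1060]
```

— the windowed Weir–Cockerham estimate recovers the simulated drift
parameter F = 0.1 inside its bootstrap interval. The `examples/`
directory holds one short script per capability (windowed diversity,
PBS scan, CNV divergence, PCA, model ranking), each printing the numbers
it computes and what they mean:

```bash
python examples/02_pbs_scan.py
```

```
mean focal PBS: 0.1046 over 200 windows
0.99-quantile threshold: 0.1724; 2 outlier windows
mean non-focal PBS: 0.0117 (lineage-specific drift is isolated on the focal branch)
```

A population drifting alone at F = 0.2 shows roughly nine-fold higher
PBS than its non-drifted sister — the lineage-specific signal the
statistic is designed to isolate.

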