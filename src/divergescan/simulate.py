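"""Synthetic populations, sex chromosomes and CNV callsets with known truth.

Population divergence follows the Balding–Nichols model: each
polymorphic site draws an ancestral frequency p uniformly on
[0.05, 0.95], and each population's frequency comes from a Beta
distribution with mean p and variance F·p(1−p), where F is the drift
parameter — so genome-wide Weir–Cockerham FST between two populations
simulated at the same F recovers a value near F.  Diploid genotypes are
independent binomial allele draws; invariant sites are emitted as
all-reference records so downstream π/dXY denominators are honest;
missingness is i.i.d. at the configured rate.

The sex-chromosome generator emulates an X analyzed in females only,
with a pseudoautosomal region (PAR) of elevated diversity, and a
male-limited haploid Y.  The PAR multiplier scales the density of
polymorphic sites, which scales expected π linearly while leaving the
allele-frequency distribution unchanged.

The CNV generator plants disjoint latent loci with per-population
carrier frequencies, then emits two caller-like callsets: every true
locus appears in both with endpoints jittered uniformly, and each
callset is padded with spurious calls (lengths resampled from the true
calls, placed away from true loci) at a configurable false-call
fraction.  A copy-number matrix drawn from the same carrier dosages ties
FST and VST to a common truth.

No linkage, recombination map, or selection is simulated: sites and loci
are exchangeable, which is exactly what makes window-level recovery
tests interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnv import CNVCall, CNVCallset, CopyNumberMatrix
from .genotypes import GenotypeMatrix, PopulationMap


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the split-population generator.

    ``divergence_F`` may be a single drift parameter shared by all
    populations or one value per population.
    """

    n_pops: int = 2
    n_diploids_per_pop: int = 20
    n_sites: int = 10_000
    seq_length: int = 1_000_000
    divergence_F: float | tuple[float, ...] = 0.1
    prop_variant: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.n_pops < 2 or self.n_pops > 3:
            raise ValueError("n_pops must be 2 or 3")
        if self.n_diploids_per_pop < 2:
            raise ValueError("need at least 2 diploids per population")
        if self.n_sites > self.seq_length:
            raise ValueError("n_sites cannot exceed seq_length")
        for f in self.f_per_pop:
            if not 0 <= f < 1:
                raise ValueError("divergence_F must lie in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0 <= self.prop_variant <= 1:
            raise ValueError("prop_variant must lie in [0, 1]")

    @property
    def f_per_pop(self) -> tuple[float, ...]:
        f = self.divergence_F
        if isinstance(f, (int, float)):
            return (float(f),) * self.n_pops
        if len(f) != self.n_pops:
            raise ValueError("divergence_F length must match n_pops")
        return tuple(float(x) for x in f)


@dataclass(frozen=True)
class SexChromParams:
    """Sex-linked simulation: PAR interval (0-based half-open on the X),
    diversity multiplier inside it, and per-population sample counts."""

    par_interval: tuple[int, int] = (0, 2_500_000)
    par_pi_multiplier: float = 1.0
    n_males: int = 10
    n_females: int = 10

    def __post_init__(self) -> None:
        if self.par_pi_multiplier < 1:
            raise ValueError("par_pi_multiplier must be >= 1")
        if self.par_interval[1] < self.par_interval[0]:
            raise ValueError("PAR interval must be non-decreasing")


@dataclass
class CNVTruthLocus:
    """A latent CNV: interval, type, and per-population carrier frequency."""

    chrom: str
    start: int
    end: int
    svtype: str
    carrier_freq: dict[str, float]

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TruthRecord:
    """Ground truth emitted alongside each simulation, sufficient to
    compute expected FST, π and VST analytically."""

    pop_freqs: np.ndarray | None = None  # (n_sites, n_pops), NaN invariant
    divergence_F: tuple[float, ...] | None = None
    variant_mask: np.ndarray | None = None
    positions: np.ndarray | None = None
    popmap: PopulationMap | None = None
    par_interval: tuple[int, int] | None = None
    cnv_loci: list[CNVTruthLocus] = field(default_factory=list)


def _balding_nichols(rng: np.random.Generator, p_anc: np.ndarray,
                     f: float) -> np.ndarray:
    """Population allele frequencies under Balding–Nichols drift F.

    Beta with mean p and variance F·p(1−p); F = 0 degenerates to a point
    mass at p.
    """
    if f == 0:
        return p_anc.copy()
    shape = (1 - f) / f
    return rng.beta(p_anc * shape, (1 - p_anc) * shape)


def _draw_calls(rng: np.random.Generator, freqs: np.ndarray, n_ind: int,
                ploidy: int) -> np.ndarray:
    """Binomial allele draws: (n_sites, n_ind, ploidy) int8."""
    u = rng.random((freqs.size, n_ind, ploidy))
    return (u < freqs[:, None, None]).astype(np.int8)


def _apply_missingness(rng: np.random.Generator, calls: np.ndarray,
                       rate: float) -> None:
    """Set whole genotypes missing i.i.d. at ``rate`` (in place)."""
    if rate <= 0:
        return
    miss = rng.random(calls.shape[:2]) < rate
    calls[miss] = -1


def _site_positions(rng: np.random.Generator, n_sites: int,
                    seq_length: int) -> np.ndarray:
    pos = rng.choice(seq_length, size=n_sites, replace=False)
    return np.sort(pos) + 1  # 1-based


def simulate_split_populations(params: SimulationParams
                               ) -> tuple[GenotypeMatrix, TruthRecord]:
    """Diploid genotypes for 2–3 populations split under drift F.

    Returns the all-sites genotype matrix (invariant records included)
    and the truth record carrying per-population frequencies.  Identical
    parameters and seed reproduce the output bit-for-bit.
    """
    rng = np.random.default_rng(params.seed)
    n_sites = params.n_sites
    pos = _site_positions(rng, n_sites, params.seq_length)
    variant = rng.random(n_sites) < params.prop_variant
    n_var = int(variant.sum())
    p_anc = rng.uniform(0.05, 0.95, size=n_var)

    pop_freqs = np.full((n_sites, params.n_pops), np.nan)
    pop_names = [f"pop{i + 1}" for i in range(params.n_pops)]
    n_ind = params.n_diploids_per_pop
    calls = np.zeros((n_sites, n_ind * params.n_pops, 2), dtype=np.int8)
    samples, pops = [], {}
    for i, (name, f) in enumerate(zip(pop_names, params.f_per_pop)):
        freqs = _balding_nichols(rng, p_anc, f)
        pop_freqs[variant, i] = freqs
        calls[variant, i * n_ind:(i + 1) * n_ind, :] = _draw_calls(
            rng, freqs, n_ind, 2)
        for j in range(n_ind):
            s = f"{name}_{j:03d}"
            samples.append(s)
            pops[s] = name
    _apply_missingness(rng, calls, params.missing_rate)

    alt = np.where(variant, "T", "").astype(object)
    gm = GenotypeMatrix(np.full(n_sites, params.chrom, dtype=object), pos,
                        np.full(n_sites, "A", dtype=object), alt, calls,
                        samples)
    truth = TruthRecord(pop_freqs=pop_freqs, divergence_F=params.f_per_pop,
                        variant_mask=variant, positions=pos,
                        popmap=PopulationMap.from_dict(pops))
    return gm, truth


def simulate_sex_chromosomes(params: SimulationParams, sex: SexChromParams
                             ) -> tuple[GenotypeMatrix,
                                        GenotypeMatrix | None,
                                        TruthRecord]:
    """An X chromosome (females, diploid, PAR-elevated diversity) and a
    haploid male-only Y.

    ``sex.n_females``/``sex.n_males`` are per-population counts.  The PAR
    multiplier scales the probability that a site is polymorphic, so
    expected π in the PAR is ``par_pi_multiplier`` times nonPAR π.  With
    n_males = 0 the Y matrix is None; with 0 < n_males < 2 per
    population the Y is refused (pairwise statistics undefined).
    """
    par_lo, par_hi = sex.par_interval
    if par_lo < 0 or par_hi > params.seq_length:
        raise ValueError("PAR interval must lie within the simulated X")
    p_par = params.prop_variant * sex.par_pi_multiplier
    if p_par > 1:
        raise ValueError("prop_variant × par_pi_multiplier exceeds 1; "
                         "lower prop_variant")
    rng = np.random.default_rng(params.seed)
    pop_names = [f"pop{i + 1}" for i in range(params.n_pops)]

    # ---- X: females only, diploid -----------------------------------
    pos = _site_positions(rng, params.n_sites, params.seq_length)
    in_par = (pos - 1 >= par_lo) & (pos - 1 < par_hi)
    p_variant = np.where(in_par, p_par, params.prop_variant)
    variant = rng.random(params.n_sites) < p_variant
    n_var = int(variant.sum())
    p_anc = rng.uniform(0.05, 0.95, size=n_var)
    pop_freqs = np.full((params.n_sites, params.n_pops), np.nan)
    calls = np.zeros((params.n_sites, sex.n_females * params.n_pops, 2),
                     dtype=np.int8)
    samples, pops, sexes = [], {}, {}
    for i, (name, f) in enumerate(zip(pop_names, params.f_per_pop)):
        freqs = _balding_nichols(rng, p_anc, f)
        pop_freqs[variant, i] = freqs
        lo = i * sex.n_females
        calls[variant, lo:lo + sex.n_females, :] = _draw_calls(
            rng, freqs, sex.n_females, 2)
        for j in range(sex.n_females):
            s = f"{name}_F{j:03d}"
            samples.append(s)
            pops[s] = name
            sexes[s] = "F"
    _apply_missingness(rng, calls, params.missing_rate)
    alt = np.where(variant, "T", "").astype(object)
    gm_x = GenotypeMatrix(np.full(params.n_sites, "chrX", dtype=object), pos,
                          np.full(params.n_sites, "A", dtype=object), alt,
                          calls, samples)

    # ---- Y: males only, haploid --------------------------------------
    gm_y = None
    if sex.n_males > 0:
        if sex.n_males < 2:
            raise ValueError("need n_males >= 2 per population for the Y")
        pos_y = _site_positions(rng, params.n_sites, params.seq_length)
        variant_y = rng.random(params.n_sites) < params.prop_variant
        n_var_y = int(variant_y.sum())
        p_anc_y = rng.uniform(0.05, 0.95, size=n_var_y)
        calls_y = np.zeros((params.n_sites, sex.n_males * params.n_pops, 1),
                           dtype=np.int8)
        for i, (name, f) in enumerate(zip(pop_names, params.f_per_pop)):
            freqs = _balding_nichols(rng, p_anc_y, f)
            lo = i * sex.n_males
            calls_y[variant_y, lo:lo + sex.n_males, :] = _draw_calls(
                rng, freqs, sex.n_males, 1)
            for j in range(sex.n_males):
                s = f"{name}_M{j:03d}"
                pops[s] = name
                sexes[s] = "M"
        _apply_missingness(rng, calls_y, params.missing_rate)
        alt_y = np.where(variant_y, "T", "").astype(object)
        gm_y = GenotypeMatrix(
            np.full(params.n_sites, "chrY", dtype=object), pos_y,
            np.full(params.n_sites, "A", dtype=object), alt_y, calls_y,
            [f"{name}_M{j:03d}" for name in pop_names
             for j in range(sex.n_males)])

    truth = TruthRecord(pop_freqs=pop_freqs, divergence_F=params.f_per_pop,
                        variant_mask=variant, positions=pos,
                        popmap=PopulationMap.from_dict(pops, sexes),
                        par_interval=sex.par_interval)
    return gm_x, gm_y, truth


# ----------------------------------------------------------------------
# CNVs
# ----------------------------------------------------------------------

def simulate_cnv_truth(n_loci: int = 100, genome_length: int = 10_000_000,
                       chrom: str = "chr1",
                       pop_names: tuple[str, str] = ("pop1", "pop2"),
                       mean_length: int = 5_000,
                       n_differentiated: int = 0,
                       base_freq: float = 0.3, seed: int = 0
                       ) -> list[CNVTruthLocus]:
    """Disjoint latent CNV loci with per-population carrier frequencies.

    The first ``n_differentiated`` loci get strongly divergent carrier
    frequencies (0.9 vs 0.05); the rest share ``base_freq`` in both
    populations up to small independent noise.
    """
    rng = np.random.default_rng(seed)
    lengths = rng.exponential(mean_length, size=n_loci).astype(int) + 50
    gap = genome_length // n_loci
    if lengths.max() >= gap:
        lengths = np.minimum(lengths, gap - 1)
    loci = []
    for i in range(n_loci):
        start = i * gap + int(rng.integers(0, gap - lengths[i]))
        svtype = "DEL" if rng.random() < 0.5 else "DUP"
        if i < n_differentiated:
            freq = {pop_names[0]: 0.9, pop_names[1]: 0.05}
        else:
            q = float(np.clip(base_freq + rng.normal(0, 0.05), 0.02, 0.98))
            freq = {pop_names[0]: q, pop_names[1]: q}
        loci.append(CNVTruthLocus(chrom, start, start + int(lengths[i]),
                                  svtype, freq))
    return loci


def _jittered(rng: np.random.Generator, locus: CNVTruthLocus,
              jitter_bp: int) -> tuple[int, int]:
    if jitter_bp == 0:
        return locus.start, locus.end
    start = locus.start + int(rng.integers(-jitter_bp, jitter_bp + 1))
    end = locus.end + int(rng.integers(-jitter_bp, jitter_bp + 1))
    start = max(0, start)
    if end <= start:
        end = start + 1
    return start, end


def simulate_cnv_callsets(truth_cnvs: list[CNVTruthLocus],
                          popmap: PopulationMap,
                          jitter_bp: int = 0,
                          fdr_a: float = 0.0, fdr_b: float = 0.0,
                          seed: int = 0,
                          genome_length: int | None = None
                          ) -> tuple[CNVCallset, CNVCallset,
                                     CopyNumberMatrix]:
    """Two jittered caller-like callsets plus the copy-number matrix.

    Per sample and true locus, carrier-allele dosage is Binomial(2, q_pop)
    — shared by both callsets, so true calls agree on genotypes.  Each
    callset contains every true locus with endpoints perturbed uniformly
    within ±``jitter_bp``, plus spurious calls (placed on CNV-free
    sequence, lengths resampled from the true calls) making up fraction
    ``fdr_a``/``fdr_b`` of that callset.
    """
    if jitter_bp < 0:
        raise ValueError("jitter_bp must be >= 0")
    for frac in (fdr_a, fdr_b):
        if not 0 <= frac < 1:
            raise ValueError("false-call fractions must lie in [0, 1)")
    ordered = sorted(truth_cnvs, key=lambda c: (c.chrom, c.start))
    for prev, cur in zip(ordered, ordered[1:]):
        if prev.chrom == cur.chrom and cur.start < prev.end:
            raise ValueError("latent CNV loci must be disjoint")
    rng = np.random.default_rng(seed)
    samples = list(popmap.table["sample"])
    sample_pop = [popmap.population_of(s) for s in samples]

    # shared truth: carrier dosage per locus × sample
    dosages = np.zeros((len(truth_cnvs), len(samples)), dtype=np.int8)
    copies = np.zeros_like(dosages, dtype=np.int64)
    for i, locus in enumerate(truth_cnvs):
        q = np.array([locus.carrier_freq[p] for p in sample_pop])
        d = rng.binomial(2, q).astype(np.int8)
        dosages[i] = d
        copies[i] = 2 - d if locus.svtype == "DEL" else 2 + d

    def build(fdr: float) -> CNVCallset:
        calls = [CNVCall(locus.chrom, *_jittered(rng, locus, jitter_bp),
                         locus.svtype, 100.0, dosages[i])
                 for i, locus in enumerate(truth_cnvs)]
        n_spurious = int(round(len(truth_cnvs) * fdr / (1 - fdr)))
        if n_spurious:
            glen = genome_length or max(c.end for c in truth_cnvs) * 2
            lengths = [c.length for c in truth_cnvs]
            margin = jitter_bp
            placed = 0
            while placed < n_spurious:
                length = int(rng.choice(lengths))
                start = int(rng.integers(0, max(1, glen - length)))
                end = start + length
                clear = all(t.chrom != truth_cnvs[0].chrom
                            or end + margin <= t.start
                            or start - margin >= t.end
                            for t in truth_cnvs)
                if not clear:
                    continue
                svtype = "DEL" if rng.random() < 0.5 else "DUP"
                gt = rng.binomial(2, 0.1, size=len(samples)).astype(np.int8)
                calls.append(CNVCall(truth_cnvs[0].chrom, start, end,
                                     svtype, 10.0, gt))
                placed += 1
        return CNVCallset(calls, samples).sorted()

    callset_a = build(fdr_a)
    callset_b = build(fdr_b)
    loci_df = pd.DataFrame(
        [(c.chrom, c.start, c.end, c.svtype) for c in truth_cnvs],
        columns=["chrom", "start", "end", "svtype"])
    return callset_a, callset_b, CopyNumberMatrix(loci_df, copies, samples)
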