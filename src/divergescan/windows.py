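"""Invariant-site-aware windowed diversity and differentiation.

π and dXY are computed as ratios of sums: per site we accumulate a
pairwise-difference numerator and a pairwise-comparison denominator, then
divide the window sums.  Including invariant sites in the denominator is
what makes the estimates absolute (per compared site) rather than
per-SNP, and it makes missing data unbiased: a site with fewer called
alleles simply contributes fewer comparisons.

FST uses the Weir & Cockerham (1984) variance-components estimator.
Per variant site we compute the among-population (a), among-individual
(b) and within-individual (c) components; a window's FST is
Σa / Σ(a+b+c).  Negative window estimates are clamped to 0, the raw
ratio is retained.  Haploid data (the Y chromosome) use the haploid
reduction: alleles are the sampling unit, heterozygosity terms vanish,
and b and c collapse into a single within-population component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, PopulationMap

DEFAULT_WINDOW = 50_000


# ----------------------------------------------------------------------
# per-site components
# ----------------------------------------------------------------------

def site_pi_components(calls: np.ndarray) -> tuple[int, int]:
    """Pairwise-difference numerator and comparison denominator for one
    population at one site.

    With n0 REF and n1 ALT called allele copies (k = n0 + n1):
    differences = n0·n1, comparisons = k(k−1)/2.  An all-missing site
    yields (0, 0).
    """
    calls = np.asarray(calls)
    n0 = int((calls == 0).sum())
    n1 = int((calls == 1).sum())
    k = n0 + n1
    return n0 * n1, k * (k - 1) // 2


def site_dxy_components(calls_a: np.ndarray, calls_b: np.ndarray
                        ) -> tuple[int, int]:
    """Between-population difference and comparison counts at one site."""
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    na0, na1 = int((a == 0).sum()), int((a == 1).sum())
    nb0, nb1 = int((b == 0).sum()), int((b == 1).sum())
    return na0 * nb1 + na1 * nb0, (na0 + na1) * (nb0 + nb1)


def site_wc_fst_components(calls_a: np.ndarray, calls_b: np.ndarray
                           ) -> tuple[float, float, float]:
    """Weir & Cockerham variance components (a, b, c) at one site.

    ``calls_a``/``calls_b`` are (n_samples, ploidy) allele arrays for the
    two populations.  Diploid data follow W&C (1984) eqs for r = 2
    populations with observed heterozygosity; individuals with any
    missing allele are excluded.  Haploid data use the haploid ANOVA
    reduction (allele copies as sampling units, c ≡ 0).  Returns NaNs
    when a population has no called individuals or n̄ ≤ 1.
    """
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    ploidy = a.shape[1]
    nan3 = (math.nan, math.nan, math.nan)
    if ploidy == 2:
        called_a = np.all(a >= 0, axis=1)
        called_b = np.all(b >= 0, axis=1)
        n1, n2 = int(called_a.sum()), int(called_b.sum())
        if n1 == 0 or n2 == 0:
            return nan3
        nbar = (n1 + n2) / 2
        if nbar <= 1:
            return nan3
        p1 = a[called_a].sum() / (2 * n1)
        p2 = b[called_b].sum() / (2 * n2)
        h1 = (a[called_a, 0] != a[called_a, 1]).mean() if n1 else 0.0
        h2 = (b[called_b, 0] != b[called_b, 1]).mean() if n2 else 0.0
        nc = 2 * nbar - (n1**2 + n2**2) / (2 * nbar)
        if nc == 0:
            return nan3
        pbar = (n1 * p1 + n2 * p2) / (2 * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (n1 * h1 + n2 * h2) / (2 * nbar)
        comp_a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 / 2 - hbar / 4) / (nbar - 1))
        comp_b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 / 2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        comp_c = hbar / 2
        return float(comp_a), float(comp_b), float(comp_c)
    # haploid: allele copies are the sampling units
    av = a[a >= 0]
    bv = b[b >= 0]
    n1, n2 = av.size, bv.size
    if n1 == 0 or n2 == 0:
        return nan3
    n_tot = n1 + n2
    if n1 < 2 or n2 < 2:
        return nan3
    p1, p2 = av.mean(), bv.mean()
    pbar = (n1 * p1 + n2 * p2) / n_tot
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # r−1 = 1
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n_tot - 2)
    nc = n_tot - (n1**2 + n2**2) / n_tot
    return float((msp - msg) / nc), float(msg), 0.0


# ----------------------------------------------------------------------
# vectorized internals
# ----------------------------------------------------------------------

def _pop_site_counts(calls: np.ndarray) -> dict[str, np.ndarray]:
    """Per-site allele/genotype summaries for one population's calls.

    ``calls``: (n_sites, n_samples, ploidy).
    """
    n0 = (calls == 0).sum(axis=(1, 2))
    n1 = (calls == 1).sum(axis=(1, 2))
    out = {"n0": n0, "n1": n1, "k": n0 + n1}
    if calls.shape[2] == 2:
        called = np.all(calls >= 0, axis=2)
        out["n_ind"] = called.sum(axis=1)
        het = (calls[:, :, 0] != calls[:, :, 1]) & called
        out["n_het"] = het.sum(axis=1)
        alt = np.where(called, (calls == 1).sum(axis=2), 0)
        out["alt_copies"] = alt.sum(axis=1)
    return out


def _wc_components_diploid(ca: dict, cb: dict) -> tuple[np.ndarray, ...]:
    with np.errstate(divide="ignore", invalid="ignore"):
        n1 = ca["n_ind"].astype(float)
        n2 = cb["n_ind"].astype(float)
        nbar = (n1 + n2) / 2
        p1 = ca["alt_copies"] / (2 * n1)
        p2 = cb["alt_copies"] / (2 * n2)
        h1 = ca["n_het"] / n1
        h2 = cb["n_het"] / n2
        nc = 2 * nbar - (n1**2 + n2**2) / (2 * nbar)
        pbar = (n1 * p1 + n2 * p2) / (2 * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (n1 * h1 + n2 * h2) / (2 * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 / 2 - hbar / 4)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 / 2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    bad = (n1 == 0) | (n2 == 0) | (nbar <= 1) | (nc == 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def _wc_components_haploid(ca: dict, cb: dict) -> tuple[np.ndarray, ...]:
    with np.errstate(divide="ignore", invalid="ignore"):
        n1 = ca["k"].astype(float)
        n2 = cb["k"].astype(float)
        n_tot = n1 + n2
        p1 = ca["n1"] / n1
        p2 = cb["n1"] / n2
        pbar = (n1 * p1 + n2 * p2) / n_tot
        msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n_tot - 2)
        nc = n_tot - (n1**2 + n2**2) / n_tot
        a = (msp - msg) / nc
        b = msg
    c = np.zeros_like(a)
    bad = (n1 < 2) | (n2 < 2)
    for arr in (a, b):
        arr[bad] = np.nan
    c[bad] = np.nan
    return a, b, c


# ----------------------------------------------------------------------
# windowed statistics
# ----------------------------------------------------------------------

def make_windows(chrom_lengths: dict[str, int], width: int = DEFAULT_WINDOW
                 ) -> pd.DataFrame:
    """Tile each chromosome from coordinate 0 with non-overlapping windows."""
    rows = []
    for chrom, length in chrom_lengths.items():
        for start in range(0, length, width):
            rows.append((chrom, start, min(start + width, length)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def windowed_stats(gm: GenotypeMatrix, popmap: PopulationMap,
                   pop_a: str, pop_b: str | None = None,
                   width: int = DEFAULT_WINDOW,
                   chrom_lengths: dict[str, int] | None = None
                   ) -> pd.DataFrame:
    """Per-window π (each population), dXY and Weir–Cockerham FST.

    Windows tile every chromosome from coordinate 0 with the given width;
    with ``chrom_lengths`` the tiling runs to the stated length and
    terminal partial windows are flagged, otherwise windows run to the
    last observed site.  π and dXY are ratio-of-sums over all sites
    (invariant included); FST is Σa / Σ(a+b+c) over variant sites, with
    negative window values clamped to 0 (``fst_raw`` keeps the ratio).
    Windows with a zero denominator carry NaN, not 0.
    """
    single_pop = pop_b is None
    idx_a = gm.sample_indices([s for s in popmap.samples_in(pop_a)
                               if s in gm.samples])
    calls_a = gm.calls[:, idx_a, :]
    ca = _pop_site_counts(calls_a)
    pi_a_num = ca["n0"] * ca["n1"]
    pi_a_den = ca["k"] * (ca["k"] - 1) // 2

    if not single_pop:
        idx_b = gm.sample_indices([s for s in popmap.samples_in(pop_b)
                                   if s in gm.samples])
        calls_b = gm.calls[:, idx_b, :]
        cb = _pop_site_counts(calls_b)
        pi_b_num = cb["n0"] * cb["n1"]
        pi_b_den = cb["k"] * (cb["k"] - 1) // 2
        dxy_num = ca["n0"] * cb["n1"] + ca["n1"] * cb["n0"]
        dxy_den = ca["k"] * cb["k"]
        if gm.ploidy == 2:
            wa, wb, wc = _wc_components_diploid(ca, cb)
        else:
            wa, wb, wc = _wc_components_haploid(ca, cb)
        variant = gm.is_variant
        use_fst = variant & np.isfinite(wa)

    # window assignment (positions are 1-based; windows 0-based half-open)
    win_idx = (gm.pos - 1) // width
    chroms = pd.unique(gm.chrom)
    rows = []
    for chrom in chroms:
        on_chrom = gm.chrom == chrom
        length = (chrom_lengths or {}).get(chrom,
                                           int(gm.pos[on_chrom].max()))
        n_windows = (length - 1) // width + 1
        for w in range(n_windows):
            in_w = on_chrom & (win_idx == w)
            start, end = w * width, min((w + 1) * width, length)
            row = {"chrom": chrom, "start": start, "end": end,
                   "partial": end - start < width,
                   "n_sites": int(in_w.sum())}
            row.update(_ratio("pi_a", pi_a_num[in_w].sum(),
                              pi_a_den[in_w].sum()))
            if not single_pop:
                row.update(_ratio("pi_b", pi_b_num[in_w].sum(),
                                  pi_b_den[in_w].sum()))
                row.update(_ratio("dxy", dxy_num[in_w].sum(),
                                  dxy_den[in_w].sum()))
                m = in_w & use_fst
                num = wa[m].sum()
                den = (wa[m] + wb[m] + wc[m]).sum()
                raw = num / den if m.any() and den != 0 else np.nan
                row["fst_raw"] = raw
                row["fst"] = (min(max(raw, 0.0), 1.0)
                              if np.isfinite(raw) else np.nan)
                row["n_variant_sites"] = int(m.sum())
            rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["pop_a"] = pop_a
    df.attrs["pop_b"] = pop_b
    return df


def _ratio(name: str, num: float, den: float) -> dict[str, float]:
    val = num / den if den > 0 else np.nan
    return {name: val, f"{name}_num": int(num), f"{name}_den": int(den)}


# ----------------------------------------------------------------------
# genome summaries
# ----------------------------------------------------------------------

@dataclass
class GenomeSummary:
    """Mean of a windowed statistic with a percentile bootstrap CI.

    Windows are the resampling unit; ``half_width`` is (hi − lo)/2, the
    "±" form genome-wide tables conventionally print.
    """

    mean: float
    ci_low: float
    ci_high: float
    n_windows: int
    n_boot: int

    @property
    def half_width(self) -> float:
        return (self.ci_high - self.ci_low) / 2


def genome_summary(values: np.ndarray, n_boot: int = 10_000,
                   seed: int | None = None) -> GenomeSummary:
    """Mean over defined windows with a 95% percentile bootstrap CI,
    resampling windows with replacement."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError("need at least 2 defined windows to summarize")
    rng = np.random.default_rng(seed)
    n = values.size
    draws = rng.integers(0, n, size=(n_boot, n))
    boot_means = values[draws].mean(axis=1)
    lo, hi = np.percentile(boot_means, [2.5, 97.5])
    return GenomeSummary(float(values.mean()), float(lo), float(hi),
                         n, n_boot)


def partition_par(stats: pd.DataFrame, par: tuple[int, int],
                  column: str = "pi_a", n_boot: int = 10_000,
                  seed: int | None = None
                  ) -> tuple[GenomeSummary | None, GenomeSummary | None]:
    """Split X-chromosome windows into PAR and nonPAR and summarize each.

    A window belongs to the PAR iff its midpoint lies inside the
    half-open ``par`` interval.  An empty partition returns None in that
    slot.
    """
    mid = (stats["start"] + stats["end"]) / 2
    in_par = (mid >= par[0]) & (mid < par[1])

    def _summ(mask: pd.Series) -> GenomeSummary | None:
        vals = stats.loc[mask, column].to_numpy()
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            return None
        return genome_summary(vals, n_boot=n_boot, seed=seed)

    return _summ(in_par), _summ(~in_par)


@dataclass
class YARatio:
    raw: float
    displayed: float  # truncated to two decimals


def ya_diversity_ratio(pi_y: float, pi_auto: float) -> YARatio:
    """Y:autosome diversity ratio, displayed truncated to two decimals.

    Truncation (not rounding) is the display convention: the raw ratio is
    preserved alongside.  Under neutrality with equal sex ratios the
    expectation is 1/4 (Y-linked N_e is a quarter of autosomal).
    """
    if pi_auto <= 0:
        raise ValueError("autosomal diversity must be positive")
    raw = pi_y / pi_auto
    displayed = math.floor(raw * 100 + 1e-12) / 100
    return YARatio(raw, displayed)
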