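"""Copy-number-variant population genetics.

A CNV segregates like a biallelic locus when scored as presence/absence
of the carrier allele, so between-population differentiation can be
measured with the same Weir–Cockerham FST used for SNPs.  Copy *numbers*
carry more information than carrier status, and VST — the copy-number
analogue of FST, (V_T − V_S)/V_T — partitions copy-number variance into
between- and within-population components.  Because CNV callers disagree
on breakpoints and produce spurious calls, a primary callset is
cross-validated against an independent secondary caller by fractional
length overlap before outlier scanning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as _scipy_stats

from .genotypes import PopulationMap
from .outliers import OutlierSet, quantile_outliers
from .windows import site_wc_fst_components

GT_REF, GT_HET, GT_HOM, GT_MISSING = 0, 1, 2, -1


@dataclass
class CNVCall:
    """One structural-variant interval with per-sample carrier genotypes.

    Coordinates are 0-based half-open.  ``genotypes`` codes carrier-allele
    dosage per sample: 0 ref, 1 het, 2 hom, -1 missing.
    """

    chrom: str
    start: int
    end: int
    svtype: str  # DEL | DUP | INV
    quality: float
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("CNV interval must satisfy end > start")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def alt_allele_count(self) -> int:
        g = self.genotypes
        return int(g[g > 0].sum())


@dataclass
class CNVCallset:
    calls: list[CNVCall]
    samples: list[str]

    def __len__(self) -> int:
        return len(self.calls)

    def of_type(self, *svtypes: str) -> "CNVCallset":
        return CNVCallset([c for c in self.calls if c.svtype in svtypes],
                          self.samples)

    def sorted(self) -> "CNVCallset":
        return CNVCallset(sorted(self.calls, key=lambda c: (c.chrom, c.start, c.end)),
                          self.samples)


@dataclass
class CopyNumberMatrix:
    """Integer copy number per locus × sample (diploid baseline 2)."""

    loci: pd.DataFrame  # columns chrom, start, end, svtype
    copies: np.ndarray  # (n_loci, n_samples), -1 missing
    samples: list[str]

    def __post_init__(self) -> None:
        self.copies = np.asarray(self.copies, dtype=np.int64)
        if self.copies.shape != (len(self.loci), len(self.samples)):
            raise ValueError("copies shape disagrees with loci/samples")
        if (self.copies < -1).any():
            raise ValueError("copy numbers must be >= 0 (or -1 for missing)")

    def to_tsv(self, path: str) -> None:
        df = self.loci.copy()
        for j, s in enumerate(self.samples):
            df[s] = self.copies[:, j]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str) -> "CopyNumberMatrix":
        df = pd.read_csv(path, sep="\t")
        meta = ["chrom", "start", "end", "svtype"]
        samples = [c for c in df.columns if c not in meta]
        return cls(df[meta].reset_index(drop=True),
                   df[samples].to_numpy(dtype=np.int64), samples)


@dataclass
class VstRecord:
    chrom: str
    start: int
    end: int
    v_total: float
    v_within: float
    vst: float  # NaN when undefined


def _genotypes_to_allele_pairs(genotypes: np.ndarray) -> np.ndarray:
    """Carrier-dosage codes → diploid allele pairs (1 site × n samples × 2)."""
    lookup = {GT_REF: (0, 0), GT_HET: (0, 1), GT_HOM: (1, 1),
              GT_MISSING: (-1, -1)}
    pairs = np.array([lookup[int(g)] for g in genotypes], dtype=np.int8)
    return pairs[np.newaxis, :, :]


def cnv_fst(callset: CNVCallset, popmap: PopulationMap,
            pop_a: str | None = None, pop_b: str | None = None) -> pd.DataFrame:
    """Per-locus Weir–Cockerham FST treating each CNV as a biallelic locus.

    The carrier allele plays the role of ALT.  Negative estimates are
    clamped to 0 (the raw ratio is kept in ``fst_raw``); loci where one
    population is entirely missing come back NaN.
    """
    pops = popmap.populations if pop_a is None else [pop_a, pop_b]
    if len(pops) != 2:
        raise ValueError("cnv_fst needs exactly two populations")
    idx_a = np.array([callset.samples.index(s) for s in popmap.samples_in(pops[0])
                      if s in callset.samples], dtype=np.intp)
    idx_b = np.array([callset.samples.index(s) for s in popmap.samples_in(pops[1])
                      if s in callset.samples], dtype=np.intp)
    rows = []
    for call in callset.calls:
        pairs = _genotypes_to_allele_pairs(call.genotypes)
        a, b, c = site_wc_fst_components(pairs[0][idx_a], pairs[0][idx_b])
        denom = a + b + c
        raw = a / denom if np.isfinite(denom) and denom != 0 else np.nan
        fst = min(max(raw, 0.0), 1.0) if np.isfinite(raw) else np.nan
        rows.append((call.chrom, call.start, call.end, call.svtype,
                     call.length, fst, raw))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "svtype",
                                       "length", "fst", "fst_raw"])


def vst(copies: np.ndarray, popmap: PopulationMap,
        samples: list[str], locus: tuple[str, int, int] = ("", 0, 1)
        ) -> VstRecord:
    """VST for one locus: (V_T − V_S) / V_T.

    ``v_total`` is the variance of copy number pooled over populations;
    ``v_within`` the population-size-weighted mean within-population
    variance (sample variances, denominator n−1, matching R's ``var``).
    Undefined (NaN) when total variance is zero or any population has
    fewer than two called samples.  Negative values are reported as-is.
    """
    copies = np.asarray(copies, dtype=float)
    copies[copies < 0] = np.nan
    per_pop = []
    for pop in popmap.populations:
        members = [s for s in popmap.samples_in(pop) if s in samples]
        vals = copies[[samples.index(s) for s in members]]
        vals = vals[~np.isnan(vals)]
        per_pop.append(vals)
    pooled = np.concatenate(per_pop)
    chrom, start, end = locus
    if any(len(v) < 2 for v in per_pop):
        return VstRecord(chrom, start, end, np.nan, np.nan, np.nan)
    v_total = float(np.var(pooled, ddof=1))
    n_total = len(pooled)
    v_within = float(sum(len(v) / n_total * np.var(v, ddof=1) for v in per_pop))
    if v_total == 0.0:
        return VstRecord(chrom, start, end, v_total, v_within, np.nan)
    return VstRecord(chrom, start, end, v_total, v_within,
                     (v_total - v_within) / v_total)


def vst_scan(cn: CopyNumberMatrix, popmap: PopulationMap) -> pd.DataFrame:
    """VST for every locus of a copy-number matrix."""
    rows = []
    for i in range(len(cn.loci)):
        loc = cn.loci.iloc[i]
        rec = vst(cn.copies[i], popmap, cn.samples,
                  (loc["chrom"], int(loc["start"]), int(loc["end"])))
        rows.append((rec.chrom, rec.start, rec.end, loc["svtype"],
                     rec.v_total, rec.v_within, rec.vst))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "svtype",
                                       "v_total", "v_within", "vst"])


def cross_validate_calls(primary: CNVCallset, secondary: CNVCallset,
                         min_overlap: float = 0.5, reciprocal: bool = False
                         ) -> tuple[CNVCallset, pd.DataFrame]:
    """Retain primary calls supported by the secondary caller.

    A primary call is kept iff some secondary call of the same svtype
    overlaps it with intersection length strictly greater than
    ``min_overlap`` × the primary call's length (and, with
    ``reciprocal=True``, also of the secondary call's length).
    Intersections use half-open coordinates.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for call in secondary.calls:
        trees.setdefault((call.chrom, call.svtype), IntervalTree()).addi(
            call.start, call.end, call)
    kept = []
    tallies: dict[str, list[int]] = {}
    for call in primary.calls:
        tallies.setdefault(call.svtype, [0, 0])[0] += 1
        tree = trees.get((call.chrom, call.svtype))
        supported = False
        if tree is not None:
            for hit in tree.overlap(call.start, call.end):
                inter = min(call.end, hit.end) - max(call.start, hit.begin)
                if inter <= min_overlap * call.length:
                    continue
                if reciprocal and inter <= min_overlap * (hit.end - hit.begin):
                    continue
                supported = True
                break
        if supported:
            kept.append(call)
            tallies[call.svtype][1] += 1
    report = pd.DataFrame(
        [(sv, n_in, n_out) for sv, (n_in, n_out) in sorted(tallies.items())],
        columns=["svtype", "n_primary", "n_retained"])
    return CNVCallset(kept, primary.samples), report


def cnv_outliers(fst_values: np.ndarray, q: float = 0.99) -> OutlierSet:
    """Loci with FST strictly above the empirical ``q`` quantile."""
    return quantile_outliers(fst_values, q)


def summarize_outlier_geometry(outliers: CNVCallset,
                               genes: list[tuple[str, int, int]]
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Length and nearest-gene geometry of outlier CNVs.

    Returns a per-call table (length, nearest-gene distance, overlap
    flag) and a per-svtype aggregate (mean/min/max length, count
    overlapping genes).  Distances are half-open gap lengths, 0 when the
    CNV intersects a gene; with no genes supplied they are NaN.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in genes:
        by_chrom.setdefault(chrom, []).append((start, end))
    rows = []
    for call in outliers.calls:
        dist = np.nan
        for gstart, gend in by_chrom.get(call.chrom, []):
            gap = max(gstart - call.end, call.start - gend, 0)
            if min(call.end, gend) > max(call.start, gstart):
                gap = 0
            dist = gap if np.isnan(dist) else min(dist, gap)
        rows.append((call.chrom, call.start, call.end, call.svtype,
                     call.length, dist, dist == 0))
    per_call = pd.DataFrame(rows, columns=["chrom", "start", "end", "svtype",
                                           "length", "nearest_gene_bp",
                                           "overlaps_gene"])
    if len(per_call):
        agg = per_call.groupby("svtype").agg(
            n=("length", "size"), mean_length=("length", "mean"),
            min_length=("length", "min"), max_length=("length", "max"),
            n_overlapping_genes=("overlaps_gene", "sum")).reset_index()
    else:
        agg = pd.DataFrame(columns=["svtype", "n", "mean_length", "min_length",
                                    "max_length", "n_overlapping_genes"])
    return per_call, agg


def fst_vst_association(fst: np.ndarray, vst_values: np.ndarray
                        ) -> tuple[float, float]:
    """Spearman rank correlation between per-locus FST and VST."""
    fst = np.asarray(fst, dtype=float)
    vst_values = np.asarray(vst_values, dtype=float)
    ok = np.isfinite(fst) & np.isfinite(vst_values)
    if ok.sum() < 10:
        raise ValueError("need at least 10 loci with both FST and VST defined")
    rho, p = _scipy_stats.spearmanr(fst[ok], vst_values[ok])
    return float(rho), float(p)
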