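"""Site, sample and ploidy filters applied between variant calling and
the divergence statistics.

Variant-quality hard filtering (QD, FS, ...) is assumed done upstream by
the caller pipeline; here we keep the population-genetic filters: the
biallelic-SNP restriction, sample- and site-level missingness cutoffs,
the minimum ALT-occurrence filter for CNV callsets, and Y-chromosome
haploidization (heterozygous male calls are artifacts on a hemizygous
chromosome and are set to missing before collapsing to haploid calls).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cnv import CNVCallset
from .genotypes import GenotypeMatrix


@dataclass
class FilterReport:
    sites_in: int
    sites_out: int
    samples_removed: list[str] = field(default_factory=list)
    tallies: dict[str, int] = field(default_factory=dict)


def filter_biallelic_snps(gm: GenotypeMatrix
                          ) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep biallelic SNP records; invariant records pass through.

    Variant records with more than one ALT allele, or with REF/ALT longer
    than one base (indels, MNPs), are removed.
    """
    bases = {"A", "C", "G", "T"}
    keep = np.ones(gm.n_sites, dtype=bool)
    tallies = {"multiallelic": 0, "non_snp": 0}
    for i in range(gm.n_sites):
        alt = gm.alt[i]
        if alt == "":
            continue
        if "," in alt:
            keep[i] = False
            tallies["multiallelic"] += 1
        elif len(alt) != 1 or len(gm.ref[i]) != 1 or alt not in bases \
                or gm.ref[i] not in bases:
            keep[i] = False
            tallies["non_snp"] += 1
    out = gm.take_sites(np.flatnonzero(keep))
    return out, FilterReport(gm.n_sites, out.n_sites, [], tallies)


def apply_missingness_filters(gm: GenotypeMatrix,
                              max_sample_missing: float = 0.1,
                              min_site_completeness: float = 0.95
                              ) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop high-missingness samples, then incomplete sites.

    Samples whose missing-genotype fraction over *variant* sites exceeds
    ``max_sample_missing`` are removed first; then any site whose called
    fraction among the remaining samples falls below
    ``min_site_completeness`` is dropped.  The order is fixed so the
    retained site set never depends on sample ordering.
    """
    if not (0 <= max_sample_missing <= 1 and 0 <= min_site_completeness <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    called = np.all(gm.calls >= 0, axis=2)  # (sites, samples)
    variant = gm.is_variant
    if variant.any():
        sample_missing = 1 - called[variant].mean(axis=0)
    else:
        sample_missing = np.zeros(gm.n_samples)
    keep_samples = sample_missing <= max_sample_missing
    removed = [s for s, k in zip(gm.samples, keep_samples) if not k]
    if not keep_samples.any():
        raise ValueError("all samples exceed the missingness threshold")
    gm2 = gm.take_samples([s for s, k in zip(gm.samples, keep_samples) if k])

    called2 = np.all(gm2.calls >= 0, axis=2)
    site_complete = called2.mean(axis=1)
    keep_sites = site_complete >= min_site_completeness
    out = gm2.take_sites(np.flatnonzero(keep_sites))
    n_dropped = int((~keep_sites).sum())
    return out, FilterReport(gm.n_sites, out.n_sites, removed,
                             {"incomplete_sites": n_dropped})


def enforce_min_alt_occurrences(calls: CNVCallset, min_count: int = 8
                                ) -> CNVCallset:
    """Drop CNV records whose total ALT (carrier) allele count across all
    samples is below ``min_count`` (het counts 1, hom counts 2)."""
    kept = [c for c in calls.calls if c.alt_allele_count >= min_count]
    return CNVCallset(kept, calls.samples)


def filter_min_quality(calls: CNVCallset, min_q: float = 1.0) -> CNVCallset:
    """Drop CNV records with quality below ``min_q``."""
    return CNVCallset([c for c in calls.calls if c.quality >= min_q],
                      calls.samples)


def filter_maf(gm: GenotypeMatrix, min_maf: float = 0.0
               ) -> tuple[GenotypeMatrix, FilterReport]:
    """Optional minor-allele-frequency filter on variant sites.

    Defaults to 0 (off): demographic analyses need the full frequency
    spectrum, so MAF filtering is opt-in.  Invariant records always pass.
    """
    if min_maf == 0:
        return gm, FilterReport(gm.n_sites, gm.n_sites, [], {"low_maf": 0})
    counts = gm.allele_counts()
    total = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(counts[:, 0], counts[:, 1]) / total
    keep = ~gm.is_variant | ((total > 0) & (maf >= min_maf))
    out = gm.take_sites(np.flatnonzero(keep))
    return out, FilterReport(gm.n_sites, out.n_sites, [],
                             {"low_maf": int((~keep).sum())})


def haploidize_y(gm: GenotypeMatrix, males: list[str]) -> GenotypeMatrix:
    """Convert diploid Y calls to haploid, males only.

    Heterozygous calls are set to missing; homozygous calls collapse to a
    single allele.  Already-haploid input passes through (idempotent).
    """
    if not males:
        raise ValueError("no male samples given")
    present = [s for s in males if s in gm.samples]
    if not present:
        raise ValueError("none of the male samples are in the matrix")
    sub = gm.take_samples(present)
    if sub.ploidy == 1:
        return sub
    a0, a1 = sub.calls[:, :, 0], sub.calls[:, :, 1]
    hap = np.where((a0 == a1), a0, -1).astype(np.int8)
    hap[(a0 < 0) | (a1 < 0)] = -1
    return GenotypeMatrix(sub.chrom, sub.pos, sub.ref, sub.alt,
                          hap[:, :, np.newaxis], present)
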