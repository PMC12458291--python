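"""All-sites VCF reading and writing.

Writing is plain VCF v4.2 text: one record per site, invariant records
with ALT ``.``, diploid GT fields like ``0/1`` and haploid fields like
``0``.  Reading goes through cyvcf2 so that anything another tool bgzips
or annotates still parses.  Coordinates are 1-based in the file and kept
1-based on the :class:`~divergescan.genotypes.GenotypeMatrix`; interval
inputs (BED) are 0-based half-open and converted at the boundary.
"""

from __future__ import annotations

import os

import numpy as np
from cyvcf2 import VCF

from .genotypes import MISSING, GenotypeMatrix

_HEADER = """\
##fileformat=VCFv4.2
##source=divergescan
{contigs}##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_allsites_vcf(gm: GenotypeMatrix, path: str,
                       contig_lengths: dict[str, int] | None = None) -> None:
    """Write a GenotypeMatrix as an all-sites VCF v4.2 text file."""
    contig_lengths = contig_lengths or {}
    contigs = []
    seen = []
    for c in gm.chrom:
        if c not in seen:
            seen.append(c)
    for c in seen:
        length = contig_lengths.get(c, int(gm.pos[gm.chrom == c].max()))
        contigs.append(f"##contig=<ID={c},length={length}>\n")
    sep = "/" if gm.ploidy == 2 else ""

    def fmt(alleles: np.ndarray) -> str:
        return sep.join("." if a == MISSING else str(int(a)) for a in alleles)

    with open(path, "w") as fh:
        fh.write(_HEADER.format(contigs="".join(contigs),
                                samples="\t".join(gm.samples)))
        for i in range(gm.n_sites):
            alt = gm.alt[i] if gm.alt[i] != "" else "."
            gts = "\t".join(fmt(gm.calls[i, j]) for j in range(gm.n_samples))
            fh.write(f"{gm.chrom[i]}\t{gm.pos[i]}\t.\t{gm.ref[i]}\t{alt}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


def read_allsites_vcf(path: str) -> GenotypeMatrix:
    """Read an all-sites VCF into a GenotypeMatrix.

    Multi-allelic records are kept (first ALT retained, extra ALT alleles
    coded as 2+) so that downstream biallelic filtering can count them;
    ploidy is taken from the first genotype encountered and must be
    uniform across the file.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    v = VCF(path, gts012=False)
    samples = list(v.samples)
    chrom, pos, ref, alt, rows = [], [], [], [], []
    ploidy = None
    for rec in v:
        gts = rec.genotypes  # [a0, phased] haploid or [a0, a1, phased] diploid
        p = len(gts[0]) - 1 if gts else 2
        if ploidy is None:
            ploidy = p
        elif ploidy != p:
            raise ValueError("mixed ploidy within one VCF is not supported")
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(",".join(rec.ALT) if rec.ALT else "")
        rows.append([g[:p] for g in gts])
    calls = np.array(rows, dtype=np.int8) if rows else np.empty(
        (0, len(samples), ploidy or 2), dtype=np.int8)
    return GenotypeMatrix(np.array(chrom, dtype=object),
                          np.array(pos, dtype=np.int64),
                          np.array(ref, dtype=object),
                          np.array(alt, dtype=object),
                          calls, samples)


def read_bed(path: str) -> list[tuple[str, int, int]]:
    """Read a BED file as (chrom, start, end) 0-based half-open tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out
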