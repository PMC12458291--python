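"""Genotype containers shared by every analysis stage.

The central object is :class:`GenotypeMatrix`: an ordered set of sites
(variant *and* invariant — invariant records are what make the π and dXY
denominators honest) crossed with a set of samples, holding integer allele
calls.  Alleles are coded 0 (REF), 1 (ALT) and -1 (missing); diploid
matrices store two allele columns per sample, haploid matrices (the Y
chromosome after haploidization) store one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Per-site × per-sample allele calls with explicit missingness.

    Parameters
    ----------
    chrom, pos, ref, alt
        Per-site arrays.  ``pos`` is 1-based (VCF convention); ``alt`` is
        ``""`` for invariant (monomorphic) records.
    calls
        ``int8`` array of shape ``(n_sites, n_samples, ploidy)`` with
        values in {0, 1, -1}.
    samples
        Sample names, unique, column order of ``calls``.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    calls: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.samples = list(self.samples)
        if self.calls.ndim != 3:
            raise ValueError("calls must have shape (n_sites, n_samples, ploidy)")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample names must be unique")
        n_sites, n_samples, ploidy = self.calls.shape
        if n_sites != len(self.pos):
            raise ValueError("site arrays and calls disagree on n_sites")
        if n_samples != len(self.samples):
            raise ValueError("samples and calls disagree on n_samples")
        if ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        # positions strictly increasing within each chromosome
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    # ------------------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.calls.shape[0]

    @property
    def n_samples(self) -> int:
        return self.calls.shape[1]

    @property
    def ploidy(self) -> int:
        return self.calls.shape[2]

    @property
    def is_variant(self) -> np.ndarray:
        """Boolean mask of sites carrying an ALT allele (SNP records)."""
        return np.array([a != "" for a in self.alt], dtype=bool)

    # ------------------------------------------------------------------
    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset to the given site indices (order-preserving)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            self.chrom[index], self.pos[index], self.ref[index],
            self.alt[index], self.calls[index], self.samples,
        )

    def take_samples(self, names: list[str]) -> "GenotypeMatrix":
        """Subset to the given samples, in the given order."""
        idx = [self.samples.index(s) for s in names]
        return GenotypeMatrix(
            self.chrom, self.pos, self.ref, self.alt,
            self.calls[:, idx, :], list(names),
        )

    def sample_indices(self, names: list[str]) -> np.ndarray:
        return np.array([self.samples.index(s) for s in names], dtype=np.intp)

    def allele_counts(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Per-site (n_ref, n_alt) called allele-copy counts.

        Returns an ``(n_sites, 2)`` int array counting 0 and 1 alleles over
        the selected samples, ignoring missing calls.
        """
        c = self.calls if sample_idx is None else self.calls[:, sample_idx, :]
        n_ref = (c == 0).sum(axis=(1, 2))
        n_alt = (c == 1).sum(axis=(1, 2))
        return np.stack([n_ref, n_alt], axis=1)

    def __eq__(self, other: object) -> bool:  # type: ignore[override]
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class PopulationMap:
    """sample → population and sample → sex assignments."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"sample", "population", "sex"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"population map needs columns {sorted(required)}")
        if self.table["sample"].duplicated().any():
            raise ValueError("duplicate samples in population map")

    @classmethod
    def from_dict(cls, pops: dict[str, str], sexes: dict[str, str] | None = None
                  ) -> "PopulationMap":
        samples = list(pops)
        sexes = sexes or {}
        return cls(pd.DataFrame({
            "sample": samples,
            "population": [pops[s] for s in samples],
            "sex": [sexes.get(s, "U") for s in samples],
        }))

    @property
    def populations(self) -> list[str]:
        return list(pd.unique(self.table["population"]))

    def samples_in(self, population: str) -> list[str]:
        t = self.table
        return list(t.loc[t["population"] == population, "sample"])

    def samples_of_sex(self, sex: str) -> list[str]:
        t = self.table
        return list(t.loc[t["sex"] == sex, "sample"])

    def population_of(self, sample: str) -> str:
        t = self.table
        return str(t.loc[t["sample"] == sample, "population"].iloc[0])

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False, header=False,
                          columns=["sample", "population", "sex"])

    @classmethod
    def read_tsv(cls, path: str) -> "PopulationMap":
        t = pd.read_csv(path, sep="\t", header=None,
                        names=["sample", "population", "sex"])
        return cls(t)
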