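"""Genotype principal component analysis.

Samples are projected onto the leading eigenvectors of the genetic
covariance matrix built from allele dosages: per variant site the ALT
dosage (0/1/2 diploid, 0/1 haploid) is mean-imputed at missing calls,
centered, and scaled by the binomial standard deviation sqrt(p(1−p))
under the site's estimated allele frequency.  Percent variance per
component comes from eigenvalue shares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix


@dataclass
class PCAResult:
    coordinates: np.ndarray  # (n_samples, n_components) unit eigenvectors
    pct_variance: np.ndarray  # per component, percent
    n_variants_used: int
    samples: list[str]


def _dosage_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Samples × variant-sites ALT dosage with NaN for missing calls."""
    variant = gm.is_variant
    calls = gm.calls[variant]  # (sites, samples, ploidy)
    missing = np.any(calls < 0, axis=2)
    dose = (calls == 1).sum(axis=2).astype(float)
    dose[missing] = np.nan
    return dose.T  # samples × sites


def genotype_pca(gm: GenotypeMatrix, n_components: int = 10) -> PCAResult:
    """PCA of a genotype matrix's variant sites.

    Sites monomorphic among called genotypes are excluded (they carry no
    variance).  Each component is sign-oriented so its largest-magnitude
    sample loading is positive, making output reproducible across
    eigensolvers.
    """
    if gm.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    dose = _dosage_matrix(gm)
    if dose.shape[1] < 2:
        raise ValueError("PCA needs at least 2 variant sites")
    ploidy = gm.ploidy
    col_mean = np.nanmean(dose, axis=0)
    p_hat = col_mean / ploidy
    poly = (p_hat > 0) & (p_hat < 1) & ~np.isnan(p_hat)
    if not poly.any():
        raise ValueError("no polymorphic sites after missing-data handling")
    dose = dose[:, poly]
    col_mean = col_mean[poly]
    p_hat = p_hat[poly]
    # mean-impute, center, scale
    nan_mask = np.isnan(dose)
    dose[nan_mask] = np.broadcast_to(col_mean, dose.shape)[nan_mask]
    z = (dose - col_mean) / np.sqrt(p_hat * (1 - p_hat))
    n_sites = z.shape[1]
    cov = z @ z.T / n_sites
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    k = min(n_components, gm.n_samples)
    coords = eigvec[:, :k]
    # orient: largest-|loading| entry positive
    for j in range(k):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    total = eigval[eigval > 0].sum()
    pct = 100 * np.maximum(eigval[:k], 0) / total
    return PCAResult(coords, pct, n_sites, list(gm.samples))
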