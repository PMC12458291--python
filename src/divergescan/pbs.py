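"""Three-population selection scan via the Population Branch Statistic.

Pairwise windowed FST values among a focal population A, a sister B and
an outgroup C are transformed into branch lengths T = −ln(1 − FST); the
focal population's branch is

    PBS_A = (T_AB + T_AC − T_BC) / 2,

clamped below at 0.  Lineage-specific drift or selection in A lengthens
both of A's pairwise branches but not the B–C branch, so PBS isolates
differentiation private to A.  Windows above the empirical 0.99 quantile
of PBS are flagged as candidate selection outliers.

Clamping order matters and is fixed: FST is clamped to 0 *before* the
log transform; PBS is clamped *after* the branch arithmetic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, PopulationMap
from .outliers import OutlierSet, quantile_outliers
from .windows import DEFAULT_WINDOW, windowed_stats

FST_CAP = 1 - 1e-6


def branch_length(fst: float | np.ndarray) -> float | np.ndarray:
    """T = −ln(1 − FST), with natural log.

    Negative inputs are clamped to 0 first; FST ≥ 1 is capped at
    1 − 1e-6 so branch lengths stay finite (see ``capped_mask`` to flag
    such windows).
    """
    f = np.clip(np.asarray(fst, dtype=float), 0.0, FST_CAP)
    t = -np.log1p(-f)
    return float(t) if np.isscalar(fst) or t.ndim == 0 else t


def capped_mask(fst: np.ndarray) -> np.ndarray:
    """Windows whose FST hit the 1 − 1e-6 cap inside branch_length."""
    return np.asarray(fst, dtype=float) >= FST_CAP


def pbs(t_ab: float | np.ndarray, t_ac: float | np.ndarray,
        t_bc: float | np.ndarray) -> float | np.ndarray:
    """Focal-population branch length ((T_AB + T_AC) − T_BC)/2, clamped
    below at 0."""
    val = (np.asarray(t_ab) + np.asarray(t_ac) - np.asarray(t_bc)) / 2
    out = np.maximum(val, 0.0)
    return float(out) if out.ndim == 0 else out


def pbs_scan(fst_ab: pd.DataFrame, fst_ac: pd.DataFrame,
             fst_bc: pd.DataFrame, focal: str = "A",
             fst_column: str = "fst") -> pd.DataFrame:
    """PBS per window from three pairwise windowed-FST tracks.

    The tracks must share a window grid (chrom/start/end); windows where
    any pair's FST is undefined are skipped and counted in
    ``df.attrs["n_skipped"]``.
    """
    key = ["chrom", "start", "end"]
    a = fst_ab[key + [fst_column]].rename(columns={fst_column: "fst_ab"})
    b = fst_ac[key + [fst_column]].rename(columns={fst_column: "fst_ac"})
    c = fst_bc[key + [fst_column]].rename(columns={fst_column: "fst_bc"})
    merged = a.merge(b, on=key).merge(c, on=key)
    if merged.empty:
        raise ValueError("the three FST tracks share no windows")
    merged = merged.sort_values(key).reset_index(drop=True)
    defined = merged[["fst_ab", "fst_ac", "fst_bc"]].notna().all(axis=1)
    n_skipped = int((~defined).sum())
    out = merged[defined].reset_index(drop=True)
    t_ab = branch_length(out["fst_ab"].to_numpy())
    t_ac = branch_length(out["fst_ac"].to_numpy())
    t_bc = branch_length(out["fst_bc"].to_numpy())
    out["t_ab"], out["t_ac"], out["t_bc"] = t_ab, t_ac, t_bc
    out["pbs"] = pbs(t_ab, t_ac, t_bc)
    out.attrs["focal"] = focal
    out.attrs["n_skipped"] = n_skipped
    return out


def pbs_from_genotypes(gm: GenotypeMatrix, popmap: PopulationMap,
                       focal: str, sister: str, outgroup: str,
                       width: int = DEFAULT_WINDOW,
                       chrom_lengths: dict[str, int] | None = None
                       ) -> pd.DataFrame:
    """Convenience path: three pairwise windowed-FST tracks computed from
    one genotype matrix, then the PBS scan."""
    kw = dict(width=width, chrom_lengths=chrom_lengths)
    fst_ab = windowed_stats(gm, popmap, focal, sister, **kw)
    fst_ac = windowed_stats(gm, popmap, focal, outgroup, **kw)
    fst_bc = windowed_stats(gm, popmap, sister, outgroup, **kw)
    return pbs_scan(fst_ab, fst_ac, fst_bc, focal=focal)


def outlier_windows(values: np.ndarray, q: float = 0.99) -> OutlierSet:
    """Windows with PBS strictly above the empirical ``q`` quantile
    (type-7 linear interpolation)."""
    return quantile_outliers(values, q)
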