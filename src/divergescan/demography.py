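"""AIC ranking of demographic-model fits and diffusion-unit scaling.

This module consumes tables of already-optimized fits (model name,
log-likelihood, free-parameter count, parameter values in diffusion
units); the likelihood optimization itself is a job for an SFS engine
and is out of scope.  Diffusion conventions follow the standard 2D-SFS
machinery: θ = 4·N_anc·μ·L, population sizes ν_i are multiples of N_anc,
time is measured in units of 2·N_anc generations, and migration
parameters M convert to per-generation fractions as M / (2·N_anc).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

_TIME_PREFIXES = ("T",)
_SIZE_PREFIXES = ("nu",)
_MIG_PREFIXES = ("m",)


@dataclass
class ModelFit:
    """One demographic model's fit: natural-log likelihood, number of
    free parameters k, and parameter values in diffusion units."""

    name: str
    log_likelihood: float
    k: int
    params: dict[str, float] = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return aic(self.log_likelihood, self.k)


@dataclass(frozen=True)
class ScalingContext:
    """Physical constants needed to leave diffusion units: per-site
    per-generation mutation rate, generation time in years, and the
    callable sequence length the SFS was built from."""

    mutation_rate: float
    generation_time: float
    sequence_length: float

    def __post_init__(self) -> None:
        if min(self.mutation_rate, self.generation_time,
               self.sequence_length) <= 0:
            raise ValueError("all scaling constants must be positive")


def aic(log_likelihood: float, k: int) -> float:
    """Akaike information criterion, 2k − 2·LL."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return 2 * k - 2 * log_likelihood


def rank_models(fits: list[ModelFit]) -> pd.DataFrame:
    """Models ordered by ascending AIC with ΔAIC to the best.

    Ties break toward the model with fewer parameters (parsimony).
    """
    if len(fits) < 2:
        raise ValueError("model comparison needs at least 2 fits")
    df = pd.DataFrame({
        "model": [f.name for f in fits],
        "log_likelihood": [f.log_likelihood for f in fits],
        "k": [f.k for f in fits],
        "aic": [f.aic for f in fits],
    })
    df = df.sort_values(["aic", "k"], kind="mergesort").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    return df


def _classify(name: str) -> str:
    if name == "theta" or name == "θ":
        return "theta"
    if name.startswith(_SIZE_PREFIXES):
        return "size"
    if name.startswith(_MIG_PREFIXES) and name != "misid":
        return "migration"
    if name.startswith(_TIME_PREFIXES):
        return "time"
    return "other"


def scale_to_natural_units(fit: ModelFit, ctx: ScalingContext
                           ) -> dict[str, float]:
    """Convert a fit's diffusion-unit parameters to natural units.

    Returns N_anc = θ/(4 μ L); each ν_i as a diploid population size
    ν_i·N_anc; each time both in generations (2·N_anc·T) and in years;
    each migration parameter as a per-generation fraction m/(2·N_anc).
    Parameters outside those families (s, misid, ...) pass through.
    """
    params = dict(fit.params)
    theta = params.pop("theta", params.pop("θ", None))
    if theta is None:
        raise ValueError("fit must include theta to anchor the scaling")
    n_anc = theta / (4 * ctx.mutation_rate * ctx.sequence_length)
    out: dict[str, float] = {"N_anc": n_anc, "theta": theta}
    for name, value in params.items():
        kind = _classify(name)
        if kind == "size":
            out[f"N_{name}"] = value * n_anc
        elif kind == "time":
            gens = 2 * n_anc * value
            out[f"{name}_generations"] = gens
            out[f"{name}_years"] = gens * ctx.generation_time
        elif kind == "migration":
            out[f"{name}_per_generation"] = value / (2 * n_anc)
        else:
            out[name] = value
    return out


def to_diffusion_units(natural: dict[str, float], ctx: ScalingContext
                       ) -> dict[str, float]:
    """Inverse of :func:`scale_to_natural_units` (round-trip identity)."""
    n_anc = natural["N_anc"]
    out: dict[str, float] = {
        "theta": 4 * n_anc * ctx.mutation_rate * ctx.sequence_length}
    for name, value in natural.items():
        if name in ("N_anc", "theta"):
            continue
        if name.startswith("N_nu"):
            out[name[2:]] = value / n_anc
        elif name.endswith("_generations"):
            out[name[:-12]] = value / (2 * n_anc)
        elif name.endswith("_years"):
            continue  # redundant with the generations entry
        elif name.endswith("_per_generation"):
            out[name[:-15]] = value * 2 * n_anc
        else:
            out[name] = value
    return out


def read_fits_tsv(path: str) -> list[ModelFit]:
    """Read fits from a TSV with columns ``model  ll  k  params`` where
    ``params`` is ``name=value;name=value;...``."""
    df = pd.read_csv(path, sep="\t")
    fits = []
    for _, row in df.iterrows():
        params = {}
        if isinstance(row.get("params"), str) and row["params"]:
            for item in row["params"].split(";"):
                name, value = item.split("=")
                params[name.strip()] = float(value)
        fits.append(ModelFit(str(row["model"]), float(row["ll"]),
                             int(row["k"]), params))
    return fits
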