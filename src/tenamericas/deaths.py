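"""Misclassification correction of tabulated deaths with simulated uncertainty.

Race and ethnicity are sometimes recorded incorrectly on death certificates
relative to self-identification, biasing race-specific mortality rates. The
correction multiplies recorded-race death counts by misclassification
ratios (self-reported / recorded deaths), propagating ratio uncertainty by
simulation:

1. deaths recorded in a multiple-race category are bridged to single races
   proportionally to the local single-race composition;
2. each published ratio gets ``n_sims`` log-normal draws, moment-matched so
   the draws' arithmetic mean equals the ratio and their SD its SE;
3. draws for different stratification dimensions (age-sex band, region,
   co-ethnic density) are combined as multiplicative deviations from the
   race-level overall ratio;
4. recorded deaths are multiplied by the combined draws, then rescaled
   within each (year, county, age, sex, simulation) so the correction never
   changes the total number of deaths — it is a population-level
   reallocation between race labels;
5. optionally, each cell is replaced by a Poisson draw with the corrected
   value as its rate, representing stochastic variation in death counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import MULTIRACE_LABEL

__all__ = [
    "MisclassificationRatio",
    "RatioDrawSet",
    "bridge_multirace_deaths",
    "draw_ratios_lognormal",
    "draw_ratio_table",
    "combine_ratio_dimensions",
    "apply_and_rescale",
    "poisson_perturb",
]


@dataclass(frozen=True)
class MisclassificationRatio:
    """One published ratio with its standard error and dimension labels."""

    race: str
    dimension: str
    level: str
    mean: float
    se: float

    def __post_init__(self):
        if self.mean <= 0:
            raise ValueError("misclassification ratio must be strictly positive")
        if self.se < 0:
            raise ValueError("ratio standard error must be non-negative")


@dataclass(frozen=True)
class RatioDrawSet:
    """``n_sims`` strictly positive simulation draws for one ratio."""

    ratio: MisclassificationRatio
    draws: np.ndarray

    def __post_init__(self):
        if (self.draws <= 0).any():
            raise ValueError("ratio draws must be strictly positive")


def bridge_multirace_deaths(deaths: pd.DataFrame, composition: pd.DataFrame | None = None,
                            multirace_label: str = MULTIRACE_LABEL) -> pd.DataFrame:
    """Reallocate multiple-race deaths to single races.

    ``composition`` gives single-race shares per (year, county_id, age_group,
    sex) in a ``share`` column; when omitted, shares are taken from the
    single-race death counts themselves. Totals are conserved exactly.
    """
    strata = ["year", "county_id", "age_group", "sex"]
    multi = deaths[deaths["race"] == multirace_label]
    single = deaths[deaths["race"] != multirace_label].copy()
    if multi.empty or multi["value"].sum() == 0:
        return single.reset_index(drop=True)

    if composition is None:
        comp = single.rename(columns={"value": "share"})[strata + ["race", "share"]]
    else:
        comp = composition[strata + ["race", "share"]]
    totals = comp.groupby(strata, observed=True)["share"].transform("sum")
    comp = comp.assign(share=comp["share"] / totals.where(totals > 0))

    alloc = multi[strata + ["value"]].merge(comp, on=strata, how="left")
    if alloc["share"].isna().any():
        missing = alloc.loc[alloc["share"].isna(), strata].drop_duplicates()
        raise ValueError(
            "multirace deaths with all-zero or missing single-race composition "
            f"in strata {missing.values.tolist()[:5]}"
        )
    alloc["value"] = alloc["value"] * alloc["share"]
    out = (
        pd.concat([single, alloc[single.columns]], ignore_index=True)
        .groupby(strata + ["race"], observed=True, as_index=False)["value"].sum()
    )
    return out[["year", "county_id", "age_group", "sex", "race", "value"]]


def draw_ratios_lognormal(mean, se, n_sims: int = 1000,
                          seed: int | np.random.Generator = 0) -> np.ndarray:
    """Log-normal ratio draws moment-matched on the arithmetic scale.

    σ² = ln(1 + se²/mean²) and μ = ln(mean) − σ²/2, so the draws have
    arithmetic mean ``mean`` and arithmetic SD ``se``. ``se = 0`` gives a
    degenerate distribution at ``mean``. ``mean`` and ``se`` may be arrays
    (draws fill the last axis).
    """
    mean = np.asarray(mean, dtype=float)
    se = np.asarray(se, dtype=float)
    if (mean <= 0).any():
        raise ValueError("ratio mean must be strictly positive")
    if (se < 0).any():
        raise ValueError("ratio se must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma2 = np.log1p(se**2 / mean**2)
    mu = np.log(mean) - sigma2 / 2.0
    z = rng.standard_normal(mean.shape + (n_sims,))
    return np.exp(mu[..., None] + np.sqrt(sigma2)[..., None] * z)


def draw_ratio_table(ratios: pd.DataFrame, n_sims: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Attach a draws array (one row per ratio) to a ratio table with
    columns (race, dimension, level, ratio, se)."""
    draws = draw_ratios_lognormal(
        ratios["ratio"].to_numpy(), ratios["se"].to_numpy(), n_sims=n_sims,
        seed=np.random.default_rng(np.random.SeedSequence([seed, 11])),
    )
    out = ratios[["race", "dimension", "level"]].copy()
    out["draws"] = list(draws)
    return out


def combine_ratio_dimensions(overall: np.ndarray,
                             components: dict[str, np.ndarray]) -> np.ndarray:
    """Combine per-dimension draws as multiplicative deviations.

    combined(s) = overall(s) × Π_d component_d(s) / overall(s). When every
    component equals the overall ratio the combination is the overall ratio;
    with a single active dimension it is that dimension's draw.
    """
    overall = np.asarray(overall, dtype=float)
    combined = overall.copy()
    for dim, comp in components.items():
        comp = np.asarray(comp, dtype=float)
        if comp.shape != overall.shape:
            raise ValueError(f"component {dim!r} draw set does not align with overall")
        combined = combined * (comp / overall)
    return combined


def combined_ratio_lookup(ratio_draws: pd.DataFrame, race: str,
                          age_band: str, sex: str, region: str,
                          density_level: str | None) -> np.ndarray:
    """Combined draws for one analysis stratum; errors name any missing piece."""
    sub = ratio_draws[ratio_draws["race"] == race]

    def _one(dimension, level):
        hit = sub[(sub["dimension"] == dimension) & (sub["level"] == level)]
        if len(hit) != 1:
            raise KeyError(
                f"no misclassification ratio for race={race!r} "
                f"{dimension}={level!r}"
            )
        return hit["draws"].iloc[0]

    overall = _one("overall", "all")
    components = {}
    if (sub["dimension"] == "age_sex").any():
        components["age_sex"] = _one("age_sex", f"{age_band}|{sex}")
    if (sub["dimension"] == "region").any():
        components["region"] = _one("region", region)
    if density_level is not None and (sub["dimension"] == "density").any():
        components["density"] = _one("density", density_level)
    return combine_ratio_dimensions(overall, components)


def apply_and_rescale(raw_deaths: np.ndarray, combined_ratios: np.ndarray,
                      stratum_ids: np.ndarray) -> np.ndarray:
    """Multiply deaths by ratio draws, then rescale within each stratum.

    ``raw_deaths`` has shape (cells,); ``combined_ratios`` (cells, n_sims);
    ``stratum_ids`` maps each cell to its (year, county, age, sex) stratum
    as a dense integer code. After rescaling, race-summed deaths within
    every stratum × simulation equal the raw totals exactly, so the
    correction reallocates deaths between races without changing totals.
    """
    raw = np.asarray(raw_deaths, dtype=float)
    ratios = np.asarray(combined_ratios, dtype=float)
    ids = np.asarray(stratum_ids)
    if ratios.shape[0] != raw.shape[0] or ids.shape[0] != raw.shape[0]:
        raise ValueError("cells of deaths, ratios and stratum ids must align")
    if (ratios <= 0).any():
        raise ValueError("combined ratios must be strictly positive")
    n_strata = int(ids.max()) + 1 if ids.size else 0
    corrected = raw[:, None] * ratios
    raw_tot = np.bincount(ids, weights=raw, minlength=n_strata)
    scale = np.empty_like(corrected)
    for s in range(corrected.shape[1]):
        corr_tot = np.bincount(ids, weights=corrected[:, s], minlength=n_strata)
        bad = (corr_tot == 0) & (raw_tot > 0)
        if bad.any():
            raise ValueError("corrected stratum total is zero where raw total is positive")
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(corr_tot > 0, raw_tot / np.where(corr_tot > 0, corr_tot, 1.0), 1.0)
        scale[:, s] = f[ids]
    return corrected * scale


def poisson_perturb(death_table: np.ndarray, seed: int = 0) -> np.ndarray:
    """Replace each cell by one Poisson draw with the cell value as rate.

    Simulations (last axis) use independent counter-derived streams from the
    root seed, so results are reproducible regardless of execution order.
    """
    rates = np.asarray(death_table, dtype=float)
    if (rates < 0).any():
        raise ValueError("Poisson rates must be non-negative")
    out = np.empty_like(rates)
    n_sims = rates.shape[-1]
    children = np.random.SeedSequence([seed, 12]).spawn(n_sims)
    for s in range(n_sims):
        rng = np.random.default_rng(children[s])
        out[..., s] = rng.poisson(rates[..., s])
    return out
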