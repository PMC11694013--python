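"""Synthetic counties, populations, deaths, and race misreporting.

This module fabricates vital-statistics inputs with the statistical
structure the downstream analysis assumes, so the whole pipeline is
testable without restricted mortality microdata:

* a county table with state, Rural–Urban Continuum Code, race-specific
  income per capita, a Black–White dissimilarity index computed from
  synthetic tract counts, NHPI share, and regional membership flags;
* a population series by year × county × age group × sex × race with a
  census-base discontinuity at a configurable year and a reported
  "Two or More Races" category from that year onward;
* death counts drawn from a Poisson law with expectation
  population × Gompertz–Makeham hazard at the age-group midpoint;
* a misreporting process that relabels each death's race on the record
  via a row-stochastic matrix, conserving stratum totals exactly;
* misclassification-ratio tables (self-reported / recorded deaths) by
  age-sex band, census region and co-ethnic density tercile, with
  delta-method standard errors.

The true (self-reported) tabulations are retained alongside the recorded
ones, which is what makes end-to-end parameter-recovery experiments
possible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ages import AgeSchema, default_abridged_schema
from .classify import CENSUS_REGIONS, US_STATES, assign_americas, validate_partition
from .config import MULTIRACE_LABEL, ConfigurationError, SyntheticConfig

__all__ = [
    "generate_counties",
    "generate_population",
    "true_population",
    "simulate_deaths",
    "apply_misreporting",
    "report_multirace_deaths",
    "derive_misclassification_ratios",
    "SyntheticVitals",
    "generate_vitals",
]

log = logging.getLogger(__name__)

# Stable age distribution used for the population pyramid (19 groups).
_AGE_WEIGHTS = np.array(
    [0.012, 0.049, 0.062, 0.064, 0.066, 0.068, 0.068, 0.066, 0.064, 0.062,
     0.063, 0.066, 0.064, 0.059, 0.050, 0.040, 0.030, 0.021, 0.026]
)
_SEX_WEIGHTS = {"female": 0.508, "male": 0.492}

# Mean county race composition for the Dirichlet composition draw.
_MEAN_SHARES = {"AIAN": 0.03, "Asian": 0.07, "Black": 0.14, "Latino": 0.16, "White": 0.60}

# Per-state probability of carrying each regional flag. Real membership
# lists (ARC, NPS Delta region) are external resources; flags are sampled.
_APPALACHIA_PROBS = {
    "WV": 1.0, "KY": 0.65, "TN": 0.5, "PA": 0.55, "OH": 0.35, "VA": 0.4,
    "NC": 0.3, "GA": 0.3, "AL": 0.45, "MS": 0.25, "MD": 0.2, "NY": 0.2, "SC": 0.2,
}
_LMV_PROBS = {"AR": 0.55, "LA": 0.6, "MS": 0.6, "TN": 0.3, "MO": 0.25, "KY": 0.25, "IL": 0.2}

# Broad age bands used for the age-sex ratio dimension.
_AGE_BANDS = ("0-24", "25-44", "45-64", "65-84", "85+")

#: Expected deaths above this level trip the overflow guard.
_MAX_EXPECTED_DEATHS = 1e12


def _age_band(age_start: float) -> str:
    if age_start < 25:
        return "0-24"
    if age_start < 45:
        return "25-44"
    if age_start < 65:
        return "45-64"
    if age_start < 85:
        return "65-84"
    return "85+"


def generate_counties(config: SyntheticConfig) -> pd.DataFrame:
    """Synthesize the county-attribute table.

    Includes, beyond the classification attributes, the latent base
    population, race composition shares, census region, and co-ethnic
    density terciles for AIAN and Latino (single stratum for other races).
    Raises :class:`ConfigurationError` if any of the ten Americas would
    receive no county×race unit.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    C = config.n_counties
    county_id = [f"C{i:05d}" for i in range(C)]
    state = rng.choice(US_STATES, size=C)
    # metro codes are less common than rural ones
    rucc = rng.choice(np.arange(1, 10), size=C,
                      p=[0.12, 0.08, 0.08, 0.10, 0.12, 0.15, 0.10, 0.15, 0.10])

    base_population = rng.lognormal(mean=np.log(25_000), sigma=1.1, size=C)
    base_population *= np.where(rucc == 1, 8.0, np.where(rucc <= 3, 3.0, 1.0))

    alpha = 8.0 * np.array([_MEAN_SHARES[r] for r in config.races])
    shares = rng.dirichlet(alpha, size=C)

    # race-specific income: below/above the national median with probability
    # low_income_fraction, uniform within each side
    incomes = {}
    from .classify import INCOME_THRESHOLD

    for j, race in enumerate(config.races):
        below = rng.random(C) < config.low_income_fraction
        lo = INCOME_THRESHOLD * (0.55 + 0.45 * rng.random(C))
        hi = INCOME_THRESHOLD * (1.0 + 1.5 * rng.random(C)) + 1.0
        incomes[race] = np.where(below, lo, hi)

    # Black-White dissimilarity from synthetic tract counts: a concentration
    # parameter controls how unevenly Black residents spread over tracts.
    n_tracts = 10
    conc = np.exp(rng.uniform(np.log(0.08), np.log(4.0), size=C))
    disim = np.empty(C)
    from .classify import dissimilarity_index

    for c in range(C):
        b_shares = rng.dirichlet(np.full(n_tracts, conc[c]))
        w_shares = rng.dirichlet(np.full(n_tracts, 12.0))
        disim[c] = dissimilarity_index(b_shares, w_shares)

    nhpi_share = rng.beta(1.5, 10.0, size=C)
    app_p = np.array([_APPALACHIA_PROBS.get(s, 0.0) for s in state])
    lmv_p = np.array([_LMV_PROBS.get(s, 0.0) for s in state])
    appalachia = rng.random(C) < app_p
    lmv = rng.random(C) < lmv_p
    deep_south = np.isin(state, ["SC", "GA", "AL", "MS", "LA"])

    df = pd.DataFrame(
        {
            "county_id": county_id,
            "state": state,
            "rucc": rucc.astype(int),
            "dissimilarity_index": disim,
            "nhpi_share": nhpi_share,
            "appalachia": appalachia,
            "lower_mississippi_valley": lmv,
            "deep_south": deep_south,
            "region": [CENSUS_REGIONS[s] for s in state],
            "base_population": base_population,
        }
    )
    for race in config.races:
        df[f"income_{race}"] = incomes[race]
    for j, race in enumerate(config.races):
        df[f"share_{race}"] = shares[:, j]
    for race in ("AIAN", "Latino"):
        if race in config.races:
            df[f"density_tercile_{race}"] = pd.qcut(
                df[f"share_{race}"], 3, labels=["T1", "T2", "T3"]
            ).astype(str)

    assignments = assign_americas(df, config.races)
    counts = assignments["america_id"].value_counts().reindex(range(1, 11), fill_value=0)
    empty = counts[counts == 0].index.tolist()
    if empty:
        raise ConfigurationError(
            f"n_counties={C} too small to populate all ten Americas; "
            f"empty Americas: {empty}"
        )
    return df


def _population_array(config: SyntheticConfig, counties: pd.DataFrame,
                      schema: AgeSchema) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smooth underlying population A[county, race, age, sex, year] plus the
    per-(county, race) growth rates and old-base error signs."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    C = len(counties)
    R = len(config.races)
    A_ages = len(schema)
    years = np.array(config.year_list)
    growth = rng.normal(0.004, 0.004, size=(C, R))
    err_sign = rng.choice([-1.0, 1.0], size=(C, R))

    base = counties["base_population"].to_numpy()[:, None] * np.stack(
        [counties[f"share_{r}"].to_numpy() for r in config.races], axis=1
    )  # (C, R)
    sex_w = np.array([_SEX_WEIGHTS[s] for s in config.sex_labels])
    gfac = (1.0 + growth)[:, :, None] ** (years - years[0])[None, None, :]  # (C,R,Y)
    A = (
        base[:, :, None, None, None]
        * _AGE_WEIGHTS[None, None, :A_ages, None, None]
        * sex_w[None, None, None, :, None]
        * gfac[:, :, None, None, :]
    )
    return A, growth, err_sign


def _long_frame(values: np.ndarray, config: SyntheticConfig, counties: pd.DataFrame,
                schema: AgeSchema, races, colname: str) -> pd.DataFrame:
    idx = pd.MultiIndex.from_product(
        [counties["county_id"], list(races), schema.labels, config.sex_labels,
         config.year_list],
        names=["county_id", "race", "age_group", "sex", "year"],
    )
    df = pd.DataFrame({colname: values.reshape(-1)}, index=idx).reset_index()
    return df[["year", "county_id", "age_group", "sex", "race", colname]]


def true_population(config: SyntheticConfig, counties: pd.DataFrame,
                    schema: AgeSchema | None = None) -> pd.DataFrame:
    """The smooth, single-race population actually at risk (no reporting
    artifacts); deaths are simulated against this series."""
    schema = schema or default_abridged_schema()
    A, _, _ = _population_array(config, counties, schema)
    return _long_frame(A, config, counties, schema, config.races, "value")


def generate_population(config: SyntheticConfig, counties: pd.DataFrame,
                        schema: AgeSchema | None = None) -> pd.DataFrame:
    """The reported population series.

    Years before ``discontinuity_year`` carry an old-base measurement error
    that grows linearly over the preceding decade and reaches ±
    ``discontinuity_scale`` just before the base date, producing an abrupt
    level shift at the base year (the postcensal/census-base discordance).
    From the base year onward a share of each race's population is reported
    in a separate "Two or More Races" category.
    """
    schema = schema or default_abridged_schema()
    A, _, err_sign = _population_array(config, counties, schema)
    years = np.array(config.year_list)
    yB = config.discontinuity_year
    w0 = max(years[0], yB - 10)

    reported = A.copy()
    if config.discontinuity_scale != 0 and years[0] < yB <= years[-1] + 1:
        w = np.clip((years - w0) / max(yB - w0, 1), 0.0, None)
        w[years >= yB] = 0.0
        err = 1.0 + config.discontinuity_scale * err_sign[:, :, None] * w[None, None, :]
        reported *= err[:, :, None, None, :]

    frames = [_long_frame(reported, config, counties, schema, config.races, "value")]
    post = years >= yB
    if post.any() and any(f > 0 for f in config.multirace_fractions.values()):
        mu = np.array([config.multirace_fractions.get(r, 0.0) for r in config.races])
        multi = (reported[:, :, :, :, post] * mu[None, :, None, None, None]).sum(axis=1)
        single = reported[:, :, :, :, post] * (1.0 - mu[None, :, None, None, None])
        # overwrite post-base single-race rows and append the multirace rows
        full = frames[0].set_index(["year", "county_id", "age_group", "sex", "race"])
        idx = pd.MultiIndex.from_product(
            [counties["county_id"], list(config.races), schema.labels,
             config.sex_labels, years[post]],
            names=["county_id", "race", "age_group", "sex", "year"],
        ).reorder_levels(["year", "county_id", "age_group", "sex", "race"])
        full.loc[idx, "value"] = single.reshape(-1)
        frames = [full.reset_index()]
        midx = pd.MultiIndex.from_product(
            [counties["county_id"], schema.labels, config.sex_labels, years[post]],
            names=["county_id", "age_group", "sex", "year"],
        )
        mdf = pd.DataFrame({"value": multi.reshape(-1)}, index=midx).reset_index()
        mdf["race"] = MULTIRACE_LABEL
        frames.append(mdf[["year", "county_id", "age_group", "sex", "race", "value"]])
    out = pd.concat(frames, ignore_index=True)
    return out[["year", "county_id", "age_group", "sex", "race", "value"]]


def simulate_deaths(population: pd.DataFrame, config: SyntheticConfig,
                    seed: int | None = None,
                    schema: AgeSchema | None = None) -> pd.DataFrame:
    """Poisson death counts tabulated by true (self-reported) race.

    Expectation is population × h(age-group midpoint) with the race- and
    sex-specific Gompertz–Makeham hazard. ``population`` must be the true
    single-race series.
    """
    schema = schema or default_abridged_schema()
    if (population["value"] < 0).any():
        raise ValueError("population must be non-negative")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    mid = dict(zip(schema.labels, schema.midpoints))

    df = population.reset_index(drop=True).copy()
    haz = np.empty(len(df))
    for (race, sex), grp in df.groupby(["race", "sex"], observed=True, sort=True):
        ages = grp["age_group"].map(mid).to_numpy(dtype=float)
        haz[grp.index] = config.hazard(race, sex, ages)
    rate = df["value"].to_numpy() * haz
    if (rate > _MAX_EXPECTED_DEATHS).any():
        raise OverflowError("expected deaths exceed overflow guard")
    df["value"] = rng.poisson(rate)
    return df


def apply_misreporting(deaths: pd.DataFrame, misreport_matrix: np.ndarray,
                       races, seed: int) -> pd.DataFrame:
    """Relabel each death's recorded race by a categorical draw.

    Input is a true-race tabulation (column ``value``); output carries both
    ``deaths_true`` and ``deaths_recorded`` per (stratum, race), with the
    per-stratum total conserved exactly — misreporting permutes labels,
    never totals.
    """
    m = np.asarray(misreport_matrix, dtype=float)
    races = list(races)
    k = len(races)
    if m.shape != (k, k) or (m < 0).any() or np.max(np.abs(m.sum(axis=1) - 1)) > 1e-12:
        raise ValueError("misreport matrix rows must be non-negative and sum to 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))

    strata = ["year", "county_id", "age_group", "sex"]
    wide = deaths.pivot_table(index=strata, columns="race", values="value",
                              aggfunc="sum", fill_value=0, observed=True)
    wide = wide.reindex(columns=races, fill_value=0)
    true = wide.to_numpy(dtype=np.int64)
    recorded = np.zeros_like(true)
    for i in range(k):
        flows = rng.multinomial(true[:, i], m[i])
        recorded += flows
    out = wide.stack().rename("deaths_true").reset_index()
    out["deaths_recorded"] = recorded.reshape(-1)
    return out


def report_multirace_deaths(records: pd.DataFrame, config: SyntheticConfig,
                            seed: int) -> pd.DataFrame:
    """Move a share of recorded deaths to "Two or More Races" for years at
    or after the census-base year (the period lacking race bridging)."""
    if not any(f > 0 for f in config.multirace_fractions.values()):
        return records
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    out = records.copy()
    post = out["year"] >= config.discontinuity_year
    mu = out["race"].map(config.multirace_fractions).fillna(0.0).to_numpy()
    moved = rng.binomial(out["deaths_recorded"].to_numpy(), np.where(post, mu, 0.0))
    out["deaths_recorded"] = out["deaths_recorded"] - moved
    multi = out.loc[post & (moved > 0)].copy()
    multi["deaths_recorded"] = moved[(post & (moved > 0)).to_numpy()]
    if multi.empty:
        return out
    grp = multi.groupby(["year", "county_id", "age_group", "sex"], observed=True)[
        "deaths_recorded"].sum().reset_index()
    grp["race"] = MULTIRACE_LABEL
    grp["deaths_true"] = 0
    return pd.concat([out, grp[out.columns]], ignore_index=True)


def derive_misclassification_ratios(records: pd.DataFrame,
                                    county_attributes: pd.DataFrame,
                                    dimensions=("age_sex", "region", "density"),
                                    schema: AgeSchema | None = None) -> pd.DataFrame:
    """Misclassification ratios (self-reported / recorded deaths) by dimension.

    For each race an overall ratio is always produced, plus one row per
    requested dimension level: broad age band × sex, census region, and
    co-ethnic density tercile (AIAN and Latino only; other races have a
    single density stratum and contribute no density rows). Standard errors
    use the delta method on a ratio of Poisson totals:
    se ≈ ratio · sqrt(1/numerator + 1/denominator). Cells with zero recorded
    deaths are excluded and logged.
    """
    schema = schema or default_abridged_schema()
    recs = records[records["race"] != MULTIRACE_LABEL].copy()
    if recs["deaths_true"].sum() == 0 and recs["deaths_recorded"].sum() == 0:
        raise ValueError("all-zero death tabulation; cannot derive ratios")
    starts = {g.label: g.start for g in schema.groups}
    recs["age_band"] = recs["age_group"].map(lambda a: _age_band(starts[a]))
    cols = ["region"] + [c for c in county_attributes.columns if c.startswith("density_tercile_")]
    recs = recs.merge(county_attributes[["county_id"] + cols], on="county_id", how="left")

    rows = []

    def _emit(race, dimension, level, sub):
        num = float(sub["deaths_true"].sum())
        den = float(sub["deaths_recorded"].sum())
        if den == 0 or num == 0:
            why = "zero recorded" if den == 0 else "zero self-reported"
            log.warning("dropping ratio cell with %s deaths: race=%s %s=%s",
                        why, race, dimension, level)
            warnings.warn(
                f"ratio cell excluded ({why} deaths): {race} {dimension}={level}"
            )
            return
        ratio = num / den
        se = ratio * np.sqrt((1.0 / num if num > 0 else 0.0) + 1.0 / den)
        rows.append({"race": race, "dimension": dimension, "level": level,
                     "ratio": ratio, "se": se,
                     "deaths_self": num, "deaths_recorded": den})

    for race, sub in recs.groupby("race", observed=True, sort=True):
        _emit(race, "overall", "all", sub)
        if "age_sex" in dimensions:
            for (band, sex), cell in sub.groupby(["age_band", "sex"], observed=True, sort=True):
                _emit(race, "age_sex", f"{band}|{sex}", cell)
        if "region" in dimensions:
            for region, cell in sub.groupby("region", observed=True, sort=True):
                _emit(race, "region", region, cell)
        if "density" in dimensions and f"density_tercile_{race}" in recs.columns:
            for terc, cell in sub.groupby(f"density_tercile_{race}", observed=True, sort=True):
                _emit(race, "density", terc, cell)
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no ratio cells could be derived")
    return out


@dataclass
class SyntheticVitals:
    """Bundle of all generated artifacts for one configuration."""

    config: SyntheticConfig
    counties: pd.DataFrame
    population: pd.DataFrame          # reported (discontinuity + multirace)
    population_true: pd.DataFrame     # smooth single-race truth
    deaths: pd.DataFrame              # recorded-race long table (pipeline input)
    death_records: pd.DataFrame       # true + recorded tabulations
    ratios: pd.DataFrame

    def write(self, out_dir) -> dict[str, int]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        files = {
            "county_attributes.csv": self.counties,
            "population.csv": self.population,
            "deaths.csv": self.deaths,
            "misclassification_ratios.csv": self.ratios,
        }
        counts = {}
        for name, df in files.items():
            df.to_csv(out / name, index=False)
            counts[name] = len(df)
        self.config.to_yaml(out / "config.yaml")
        return counts


def generate_vitals(config: SyntheticConfig,
                    schema: AgeSchema | None = None) -> SyntheticVitals:
    """Run the full generator: counties → population → deaths → misreporting
    → multirace reporting → ratio tables."""
    schema = schema or default_abridged_schema()
    counties = generate_counties(config)
    pop_reported = generate_population(config, counties, schema)
    pop_true = true_population(config, counties, schema)
    deaths_true = simulate_deaths(pop_true, config, schema=schema)
    records = apply_misreporting(deaths_true, config.misreport_matrix,
                                 config.races, config.seed)
    records = report_multirace_deaths(records, config, config.seed)
    ratios = derive_misclassification_ratios(records, counties, schema=schema)
    deaths = records.rename(columns={"deaths_recorded": "value"})[
        ["year", "county_id", "age_group", "sex", "race", "value"]
    ]
    return SyntheticVitals(
        config=config,
        counties=counties,
        population=pop_reported,
        population_true=pop_true,
        deaths=deaths,
        death_records=records,
        ratios=ratios,
    )
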