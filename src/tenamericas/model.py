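"""Model/results interface for the ten-Americas mortality analysis.

:class:`TenAmericas` is built from tabulated deaths, a population series,
county attributes and (optionally) misclassification-ratio tables. Its
:meth:`~TenAmericas.fit` runs the full estimation:

1. harmonise the population (reallocate "Two or More Races", remove the
   census-base discontinuity by intercensal blending);
2. bridge multiple-race deaths to single races;
3. draw ``n_sims`` log-normal simulations of every misclassification ratio,
   combine them across dimensions, correct recorded deaths and rescale so
   stratum totals are unchanged;
4. assign each county × race unit to its America and pool deaths and
   population by America × year × age × sex × simulation;
5. add Poisson stochastic variation to the pooled death counts;
6. build abridged life tables per America × year × sex × simulation and
   extract life expectancy at birth, partial life expectancies for five
   age ranges, and remaining life expectancy at 85;
7. summarise the simulations into point estimates (means) and 95%
   uncertainty intervals (2.5th–97.5th percentiles).

The returned :class:`TenAmericasResults` carries the tidy estimates table,
per-quantity draw arrays, and gap/change/ranking helpers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ages import AgeSchema, default_abridged_schema
from .classify import assign_americas, validate_partition
from .config import MULTIRACE_LABEL, SyntheticConfig
from .deaths import (
    apply_and_rescale,
    bridge_multirace_deaths,
    combine_ratio_dimensions,
    draw_ratios_lognormal,
    poisson_perturb,
)
from .lifetable import build_life_table, life_expectancy_quantities
from .population import intercensal_blend, split_two_or_more_races
from .report import compute_change, compute_gap, disparity_report, rank_americas
from .synthetic import _age_band, generate_vitals

__all__ = ["TenAmericas", "TenAmericasResults"]

_SEX_GROUPS = ("both", "female", "male")
_KEY = ["year", "county_id", "age_group", "sex", "race"]


def _combined_draw_matrix(ratios: pd.DataFrame, combos: pd.DataFrame,
                          n_sims: int, seed: int) -> np.ndarray:
    """Combined ratio draws, one row per (race, age_band, sex, region,
    density) combination in ``combos``."""
    draws = draw_ratios_lognormal(
        ratios["ratio"].to_numpy(), ratios["se"].to_numpy(), n_sims=n_sims,
        seed=np.random.default_rng(np.random.SeedSequence([seed, 11])),
    )
    table = {
        (r.race, r.dimension, r.level): draws[i]
        for i, r in enumerate(ratios.itertuples())
    }
    dims_present = {
        race: set(sub["dimension"]) for race, sub in ratios.groupby("race")
    }
    out = np.ones((len(combos), n_sims))
    for i, row in enumerate(combos.itertuples()):
        present = dims_present.get(row.race)
        if present is None:
            continue  # race without any published ratio: no correction
        try:
            overall = table[(row.race, "overall", "all")]
        except KeyError:
            raise KeyError(f"no overall misclassification ratio for race {row.race!r}")
        # a dimension level absent from the published table (e.g. a cell
        # excluded for zero deaths) contributes no deviation from overall
        components = {}
        if "age_sex" in present:
            key = (row.race, "age_sex", f"{row.age_band}|{row.sex}")
            if key in table:
                components["age_sex"] = table[key]
            else:
                warnings.warn(f"no age-sex ratio for {key}; using overall")
        if "region" in present:
            key = (row.race, "region", row.region)
            if key in table:
                components["region"] = table[key]
            else:
                warnings.warn(f"no region ratio for {key}; using overall")
        if "density" in present and row.density != "all":
            key = (row.race, "density", row.density)
            if key in table:
                components["density"] = table[key]
            else:
                warnings.warn(f"no density ratio for {key}; using overall")
        out[i] = combine_ratio_dimensions(overall, components)
    return out


class TenAmericas:
    """Ten-Americas life-expectancy model over stratified vital statistics.

    Parameters
    ----------
    deaths : DataFrame
        Recorded deaths, long format (year, county_id, age_group, sex,
        race, value); may include a multiple-race category.
    population : DataFrame
        Population series in the same layout; may include a multiple-race
        category and a census-base discontinuity.
    county_attributes : DataFrame
        Classification attributes per county (see :mod:`tenamericas.classify`),
        plus ``region`` and any ``density_tercile_<race>`` columns used by
        the ratio dimensions.
    ratios : DataFrame, optional
        Misclassification ratios (race, dimension, level, ratio, se). When
        omitted, no correction is applied.
    """

    def __init__(self, deaths: pd.DataFrame, population: pd.DataFrame,
                 county_attributes: pd.DataFrame, ratios: pd.DataFrame | None = None,
                 schema: AgeSchema | None = None,
                 multirace_label: str = MULTIRACE_LABEL):
        self.deaths = deaths
        self.population = population
        self.county_attributes = county_attributes
        self.ratios = ratios
        self.schema = schema or default_abridged_schema()
        self.multirace_label = multirace_label

    @classmethod
    def from_synthetic(cls, config: SyntheticConfig) -> "TenAmericas":
        """Generate synthetic vital statistics and build the model on them."""
        vit = generate_vitals(config)
        return cls(vit.deaths, vit.population, vit.counties, vit.ratios)

    # ------------------------------------------------------------------

    def fit(self, n_sims: int = 1000, seed: int = 0, *,
            correct_misclassification: bool = True, poisson: bool = True,
            base_year: int | None = None, blend: str = "linear_additive",
            terminal_strategy: str = "constant_hazard",
            max_chunk_floats: float = 4e7) -> "TenAmericasResults":
        """Run the estimation and return results.

        ``base_year`` triggers the intercensal blend of the population
        series onto that census base. ``correct_misclassification=False``
        skips the ratio correction (diagnostic); ``poisson=False`` skips the
        stochastic-variation layer.
        """
        schema = self.schema
        pop = split_two_or_more_races(self.population, multirace_label=self.multirace_label)
        if base_year is not None:
            pop = intercensal_blend(pop, base_year=base_year, method=blend).frame

        comp = pop.rename(columns={"value": "share"})[_KEY[:4] + ["race", "share"]]
        deaths = bridge_multirace_deaths(self.deaths, composition=comp,
                                         multirace_label=self.multirace_label)

        attrs = self.county_attributes
        assignments = assign_americas(attrs, races=sorted(deaths["race"].unique()))
        validate_partition(assignments)

        cells = deaths.merge(assignments, on=["county_id", "race"], how="left")
        if cells["america_id"].isna().any():
            bad = cells.loc[cells["america_id"].isna(), ["county_id", "race"]].drop_duplicates()
            raise ValueError(f"units without an America assignment: {bad.values.tolist()[:5]}")

        years = np.sort(deaths["year"].unique())
        sexes = np.sort(deaths["sex"].unique())
        n_ages = len(schema)
        y_idx = cells["year"].map({y: i for i, y in enumerate(years)}).to_numpy()
        a_idx = cells["america_id"].to_numpy(dtype=int) - 1
        g_idx = cells["age_group"].map({g: i for i, g in enumerate(schema.labels)}).to_numpy()
        s_idx = cells["sex"].map({s: i for i, s in enumerate(sexes)}).to_numpy()
        c_idx = cells["county_id"].map(
            {c: i for i, c in enumerate(attrs["county_id"])}
        ).to_numpy()

        dims = (10, len(years), n_ages, len(sexes))
        agg_id = np.ravel_multi_index((a_idx, y_idx, g_idx, s_idx), dims)
        stratum_id = np.ravel_multi_index(
            (y_idx, c_idx, g_idx, s_idx), (len(years), len(attrs), n_ages, len(sexes))
        )
        stratum_id = pd.factorize(stratum_id)[0]
        raw = cells["value"].to_numpy(dtype=float)
        G = int(np.prod(dims))

        D = np.empty((G, n_sims))
        if correct_misclassification and self.ratios is not None and len(self.ratios):
            lookup = attrs.set_index("county_id")
            combo = pd.DataFrame({
                "race": cells["race"].to_numpy(),
                "age_band": cells["age_group"].map(
                    {g.label: _age_band(g.start) for g in schema.groups}
                ).to_numpy(),
                "sex": cells["sex"].to_numpy(),
                "region": lookup["region"].to_numpy()[c_idx],
            })
            density = np.full(len(cells), "all", dtype=object)
            for race in cells["race"].unique():
                col = f"density_tercile_{race}"
                if col in attrs.columns:
                    mask = (combo["race"] == race).to_numpy()
                    density[mask] = lookup[col].to_numpy()[c_idx[mask]]
            combo["density"] = density
            combo_codes, combo_unique = pd.factorize(
                pd.MultiIndex.from_frame(combo), sort=False
            )
            combos = pd.DataFrame(list(combo_unique), columns=combo.columns)
            combo_draws = _combined_draw_matrix(self.ratios, combos, n_sims, seed)

            chunk = max(1, int(max_chunk_floats / max(len(cells), 1)))
            for start in range(0, n_sims, chunk):
                stop = min(start + chunk, n_sims)
                ratios_chunk = combo_draws[combo_codes, start:stop]
                corrected = apply_and_rescale(raw, ratios_chunk, stratum_id)
                for j, s in enumerate(range(start, stop)):
                    D[:, s] = np.bincount(agg_id, weights=corrected[:, j], minlength=G)
        else:
            base = np.bincount(agg_id, weights=raw, minlength=G)
            D[:] = base[:, None]

        pop_assigned = pop[pop["year"].isin(years)].merge(
            assignments, on=["county_id", "race"], how="inner"
        )
        P = self._pop_weights(pop_assigned, years, sexes, schema)

        if poisson:
            D = poisson_perturb(D, seed=seed)

        D = D.reshape(*dims, n_sims)
        P = P.reshape(*dims)

        # sex groups: both = sum over the sex axis
        D_groups = {"both": D.sum(axis=3)}
        P_groups = {"both": P.sum(axis=3)}
        for i, s in enumerate(sexes):
            D_groups[str(s)] = D[:, :, :, i]
            P_groups[str(s)] = P[:, :, :, i]

        frames = []
        draws_store: dict[tuple[str, str], np.ndarray] = {}
        for sex_group in _SEX_GROUPS:
            if sex_group not in D_groups:
                continue
            Dg, Pg = D_groups[sex_group], P_groups[sex_group]
            if ((Pg == 0) & (Dg.sum(axis=-1) > 0)).any():
                raise ValueError("zero population with nonzero deaths at America level")
            with np.errstate(divide="ignore", invalid="ignore"):
                m = np.where(Pg[..., None] > 0, Dg / np.where(Pg[..., None] > 0, Pg[..., None], 1.0), 0.0)
            # life tables want ages on the last axis: (A, Y, sims, ages)
            m = np.moveaxis(m, 2, -1)
            lt = build_life_table(m, schema, terminal_strategy=terminal_strategy)
            for q, vals in life_expectancy_quantities(lt).items():
                draws_store[(sex_group, q)] = vals  # (A, Y, sims)
                mean = vals.mean(axis=-1)
                lo, hi = np.percentile(vals, [2.5, 97.5], axis=-1)
                idx = pd.MultiIndex.from_product(
                    [range(1, 11), years], names=["america_id", "year"]
                )
                frames.append(pd.DataFrame({
                    "america_id": idx.get_level_values(0),
                    "year": idx.get_level_values(1),
                    "sex": sex_group,
                    "quantity": q,
                    "mean": mean.reshape(-1),
                    "lower": lo.reshape(-1),
                    "upper": hi.reshape(-1),
                }))
        frame = pd.concat(frames, ignore_index=True)
        return TenAmericasResults(
            frame=frame, draws=draws_store, years=list(map(int, years)),
            n_sims=n_sims, seed=seed, schema=schema,
            corrected=correct_misclassification and self.ratios is not None,
            poisson=poisson,
        )

    @staticmethod
    def _pop_weights(pop_assigned: pd.DataFrame, years, sexes, schema) -> np.ndarray:
        """Population values re-ordered to the same ravel layout as deaths."""
        y = pop_assigned["year"].map({y: i for i, y in enumerate(years)}).to_numpy()
        a = pop_assigned["america_id"].to_numpy(dtype=int) - 1
        g = pop_assigned["age_group"].map(
            {lbl: i for i, lbl in enumerate(schema.labels)}
        ).to_numpy()
        s = pop_assigned["sex"].map({s: i for i, s in enumerate(sexes)}).to_numpy()
        dims = (10, len(years), len(schema), len(sexes))
        flat = np.zeros(int(np.prod(dims)))
        np.add.at(flat, np.ravel_multi_index((a, y, g, s), dims),
                  pop_assigned["value"].to_numpy(dtype=float))
        return flat

    def __repr__(self) -> str:  # pragma: no cover
        return (f"TenAmericas(deaths={len(self.deaths)} rows, "
                f"population={len(self.population)} rows, "
                f"counties={len(self.county_attributes)}, "
                f"ratios={'yes' if self.ratios is not None else 'no'})")


@dataclass
class TenAmericasResults:
    """Estimates with uncertainty from a fitted ten-Americas model.

    ``frame`` is tidy: (america_id, year, sex, quantity, mean, lower,
    upper) with quantity in {e0, ple_0_4, ple_5_24, ple_25_44, ple_45_64,
    ple_65_84, e85}; ``draws`` maps (sex, quantity) to the underlying
    (America × year × simulation) draw arrays.
    """

    frame: pd.DataFrame
    draws: dict[tuple[str, str], np.ndarray]
    years: list[int]
    n_sims: int
    seed: int
    schema: AgeSchema
    corrected: bool = True
    poisson: bool = True
    _grids: dict = field(default_factory=dict, repr=False)

    def grid(self, quantity: str = "e0", sex: str = "both") -> pd.DataFrame:
        """America × year grid of point estimates for one quantity."""
        key = (quantity, sex)
        if key not in self._grids:
            sub = self.frame[(self.frame["quantity"] == quantity) & (self.frame["sex"] == sex)]
            if sub.empty:
                raise KeyError(f"no results for quantity={quantity!r}, sex={sex!r}")
            self._grids[key] = sub.pivot(index="america_id", columns="year", values="mean")
        return self._grids[key]

    def gap(self, year: int, quantity: str = "e0", sex: str = "both"):
        return compute_gap(self.grid(quantity, sex), year)

    def change(self, america_id: int, year_from: int, year_to: int,
               quantity: str = "e0", sex: str = "both") -> float:
        return compute_change(self.grid(quantity, sex), america_id, year_from, year_to)

    def rank(self, year: int, quantity: str = "e0", sex: str = "both") -> pd.Series:
        return rank_americas(self.grid(quantity, sex), year)

    def disparity_report(self, periods=(), quantity: str = "e0", sex: str = "both"):
        return disparity_report(self.grid(quantity, sex), periods=periods)

    def summary(self, quantity: str = "e0", sex: str = "both",
                years: list[int] | None = None) -> str:
        """Readable table of point estimates and 95% UIs."""
        years = years or self.years
        sub = self.frame[
            (self.frame["quantity"] == quantity)
            & (self.frame["sex"] == sex)
            & (self.frame["year"].isin(years))
        ]
        lines = [
            f"Ten Americas — {quantity} ({sex}), {self.n_sims} simulations, seed {self.seed}",
            f"{'America':>8}" + "".join(f"{y:>22}" for y in years),
        ]
        for america in range(1, 11):
            row = sub[sub["america_id"] == america].set_index("year")
            cells = []
            for y in years:
                if y in row.index:
                    r = row.loc[y]
                    cells.append(f"{r['mean']:6.1f} ({r['lower']:5.1f}-{r['upper']:5.1f})")
                else:
                    cells.append("--")
            lines.append(f"{america:>8}" + "".join(f"{c:>22}" for c in cells))
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def plot(self, quantity: str = "e0", sex: str = "both", ax=None):
        """Trend lines per America with shaded 95% uncertainty bands."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 5))
        sub = self.frame[(self.frame["quantity"] == quantity) & (self.frame["sex"] == sex)]
        for america, grp in sub.groupby("america_id"):
            grp = grp.sort_values("year")
            ax.plot(grp["year"], grp["mean"], label=f"America {america}")
            ax.fill_between(grp["year"], grp["lower"], grp["upper"], alpha=0.15)
        ax.set_xlabel("year")
        ax.set_ylabel(quantity)
        ax.legend(fontsize=7, ncol=2)
        return ax
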