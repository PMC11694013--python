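"""Harmonisation of the population series.

Two artifacts of real population data are handled here: a reported
"Two or More Races" category (present only in census-base years) that must
be reallocated to the single-race groups used throughout the analysis, and
the discordance between postcensal estimates carried forward from an old
census base and the estimates anchored on the next census ("error of
closure"), removed by distributing the base-date discrepancy back over the
preceding decade in the style of intercensal estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import MULTIRACE_LABEL

__all__ = ["split_two_or_more_races", "intercensal_blend", "BlendResult"]

log = logging.getLogger(__name__)

_STRATA = ["year", "county_id", "age_group", "sex"]


def split_two_or_more_races(population: pd.DataFrame,
                            composition: pd.DataFrame | None = None,
                            multirace_label: str = MULTIRACE_LABEL) -> pd.DataFrame:
    """Allocate multiple-race population to single races proportionally.

    ``composition`` (columns ``_STRATA + [race, share]``) defaults to the
    local single-race composition of the series itself. The per-cell total
    population is conserved exactly.
    """
    multi = population[population["race"] == multirace_label]
    single = population[population["race"] != multirace_label].copy()
    if multi.empty or multi["value"].sum() == 0:
        return single.reset_index(drop=True)

    if composition is None:
        comp = single.rename(columns={"value": "share"})[_STRATA + ["race", "share"]]
    else:
        comp = composition[_STRATA + ["race", "share"]]
    totals = comp.groupby(_STRATA, observed=True)["share"].transform("sum")
    comp = comp.assign(share=comp["share"] / totals.where(totals > 0))

    alloc = multi[_STRATA + ["value"]].merge(comp, on=_STRATA, how="left")
    if alloc["share"].isna().any():
        missing = alloc.loc[alloc["share"].isna(), _STRATA].drop_duplicates()
        raise ValueError(
            "multirace population present where single-race composition is "
            f"undefined: {missing.values.tolist()[:5]}"
        )
    alloc["value"] = alloc["value"] * alloc["share"]
    out = (
        pd.concat([single, alloc[single.columns]], ignore_index=True)
        .groupby(_STRATA + ["race"], observed=True, as_index=False)["value"].sum()
    )
    return out[["year", "county_id", "age_group", "sex", "race", "value"]]


@dataclass
class BlendResult:
    """Blended series plus bookkeeping: the per-cell base-date discrepancy
    and the number of cells floored at zero."""

    frame: pd.DataFrame
    discrepancy: pd.DataFrame
    n_floored: int


def _extrapolate_old(series: pd.DataFrame, base_year: int) -> pd.Series:
    """Log-linear extrapolation of the old series to the base date from its
    last two pre-base years, per (county, age, sex, race) cell."""
    keys = ["county_id", "age_group", "sex", "race"]
    y1 = series[series["year"] == base_year - 1].set_index(keys)["value"]
    y2 = series[series["year"] == base_year - 2].set_index(keys)["value"]
    y1, y2 = y1.align(y2, join="outer")
    with np.errstate(divide="ignore", invalid="ignore"):
        growth = np.where((y2 > 0) & (y1 > 0), y1 / y2, 1.0)
    return y1.fillna(0.0) * growth


def intercensal_blend(population: pd.DataFrame, base_year: int,
                      window_start: int | None = None,
                      discrepancy: pd.DataFrame | None = None,
                      method: str = "linear_additive") -> BlendResult:
    """Remove the census-base discontinuity by blending over a window.

    The discrepancy at the base date is (new-base value − old-series value
    extrapolated to the base date), computed per (county, age, sex, race)
    cell unless supplied (columns ``county_id, age_group, sex, race,
    discrepancy``). For years t in [window_start, base_year] the adjusted
    series is old(t) + w(t)·discrepancy with w linear from 0 at the window
    start to 1 at the base date (``linear_additive``), or
    old(t)·(new/old-extrapolated)^w(t) (``linear_multiplicative``). The
    blended old series meets the new base exactly at the base date; cells
    driven negative are floored at 0 and counted.
    """
    years = population["year"].unique()
    if base_year not in years:
        raise ValueError(f"base year {base_year} outside the population series")
    if method not in ("linear_additive", "linear_multiplicative"):
        raise ValueError(f"unknown blend method {method!r}")
    window_start = int(years.min()) if window_start is None else window_start
    if not window_start < base_year:
        raise ValueError("blend window must start before the base year")

    keys = ["county_id", "age_group", "sex", "race"]
    old_ext = _extrapolate_old(population, base_year)
    new_base = (
        population[population["year"] == base_year].set_index(keys)["value"]
        .reindex(old_ext.index, fill_value=0.0)
    )
    if discrepancy is None:
        disc = new_base - old_ext
    else:
        disc = discrepancy.set_index(keys)["discrepancy"].reindex(old_ext.index, fill_value=0.0)

    out = population.copy()
    in_window = (out["year"] >= window_start) & (out["year"] < base_year)
    w = (out.loc[in_window, "year"] - window_start) / (base_year - window_start)
    idx = pd.MultiIndex.from_frame(out.loc[in_window, keys])
    if method == "linear_additive":
        adj = out.loc[in_window, "value"].to_numpy() + w.to_numpy() * disc.reindex(idx).fillna(0.0).to_numpy()
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = ((new_base / old_ext.where(old_ext > 0))
                      .fillna(1.0).replace([np.inf, -np.inf], 1.0))
        adj = out.loc[in_window, "value"].to_numpy() * (
            factor.reindex(idx).fillna(1.0).to_numpy() ** w.to_numpy()
        )
    n_floored = int((adj < 0).sum())
    if n_floored:
        log.warning("intercensal blend floored %d cells at zero", n_floored)
    out.loc[in_window, "value"] = np.maximum(adj, 0.0)
    disc_frame = disc.rename("discrepancy").reset_index()
    return BlendResult(frame=out, discrepancy=disc_frame, n_floored=n_floored)
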