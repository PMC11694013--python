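"""Disparity statistics: gaps, period changes, and rankings.

Operates on a life-expectancy grid — point estimates (years) indexed by
America (1–10) with one column per year. The packaged fixture
(:func:`load_published_life_expectancy`) carries the published point
estimates and 95% uncertainty intervals for 2000, 2010, 2019, 2020 and
2021 together with the published period changes, giving the reporting
operations an externally anchored test surface independent of simulation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "load_published_life_expectancy",
    "published_grid",
    "published_population_share",
    "POPULATION_2021_MILLIONS",
    "NATIONAL_POPULATION_2021_MILLIONS",
    "compute_gap",
    "compute_change",
    "rank_americas",
    "disparity_report",
    "round_half_away",
    "DisparityReport",
]

#: 2021 population (millions) of each America, and the national total.
POPULATION_2021_MILLIONS: dict[int, float] = {
    1: 20.67,
    2: 46.17,
    3: 1.47 + 1.07 + 190.66,  # AIAN + Asian/NHPI + White components
    4: 0.29,
    5: 16.47,
    6: 31.78,
    7: 10.26,
    8: 10.34,
    9: 2.13,
    10: 1.32,
}
NATIONAL_POPULATION_2021_MILLIONS: float = 332.64


def round_half_away(x, decimals: int = 1):
    """Round half away from zero (display convention for reported values)."""
    x = np.asarray(x, dtype=float)
    factor = 10.0**decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return float(out) if out.ndim == 0 else out


def published_population_share(america_id: int, decimals: int = 2) -> float:
    """Share (%) of the 2021 national population in one America."""
    share = 100.0 * POPULATION_2021_MILLIONS[america_id] / NATIONAL_POPULATION_2021_MILLIONS
    return round_half_away(share, decimals)


def load_published_life_expectancy() -> pd.DataFrame:
    """Tidy published estimates: america_id, quantity, mean, lower, upper.

    Quantities are ``e0_<year>`` levels and ``change_<y0>_<y1>`` period
    changes, each with its 95% uncertainty interval.
    """
    ref = importlib.resources.files("tenamericas.data") / "published_life_expectancy.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def published_grid() -> pd.DataFrame:
    """Published life expectancy at birth as an America × year grid."""
    df = load_published_life_expectancy()
    levels = df[df["quantity"].str.startswith("e0_")].copy()
    levels["year"] = levels["quantity"].str.removeprefix("e0_").astype(int)
    grid = levels.pivot(index="america_id", columns="year", values="mean")
    grid.index.name = "america_id"
    return grid


def _column(grid: pd.DataFrame, year: int) -> pd.Series:
    if year not in grid.columns:
        raise KeyError(f"year {year} not present in the grid")
    col = grid[year]
    missing = col.index[col.isna()].tolist()
    if missing:
        raise ValueError(f"missing point estimates for Americas {missing} in {year}")
    return col


def compute_gap(grid: pd.DataFrame, year: int) -> tuple[float, list[int], list[int]]:
    """Highest-minus-lowest life expectancy in a year.

    Returns (gap, argmax ids, argmin ids); ties are all listed, lowest
    America id first.
    """
    col = _column(grid, year)
    hi, lo = col.max(), col.min()
    argmax = sorted(col.index[col == hi].tolist())
    argmin = sorted(col.index[col == lo].tolist())
    return float(hi - lo), argmax, argmin


def compute_change(grid: pd.DataFrame, america_id: int, year_from: int, year_to: int) -> float:
    """value(year_to) − value(year_from) for one America."""
    for y in (year_from, year_to):
        if y not in grid.columns or america_id not in grid.index:
            raise KeyError(f"missing cell (america {america_id}, year {y})")
        if pd.isna(grid.loc[america_id, y]):
            raise ValueError(f"missing point estimate (america {america_id}, year {y})")
    return float(grid.loc[america_id, year_to] - grid.loc[america_id, year_from])


def rank_americas(grid: pd.DataFrame, year: int) -> pd.Series:
    """Dense ranks, 1 = highest life expectancy; ties share the lower rank."""
    col = _column(grid, year)
    ranks = col.rank(method="min", ascending=False).astype(int)
    ranks.name = f"rank_{year}"
    return ranks.sort_index()


@dataclass
class DisparityReport:
    """Per-year gap statistics and rankings plus per-America period changes."""

    gaps: pd.DataFrame
    changes: pd.DataFrame
    ranks: pd.DataFrame
    ties: dict = field(default_factory=dict)


def disparity_report(grid: pd.DataFrame,
                     periods: tuple[tuple[int, int], ...] = ()) -> DisparityReport:
    gap_rows = []
    rank_cols = {}
    ties = {}
    for year in grid.columns:
        gap, amax, amin = compute_gap(grid, year)
        gap_rows.append({"year": year, "max": float(grid[year].max()),
                         "min": float(grid[year].min()),
                         "argmax": amax[0], "argmin": amin[0], "gap": gap})
        r = rank_americas(grid, year)
        rank_cols[year] = r
        tied = r[r.duplicated(keep=False)]
        if not tied.empty:
            ties[year] = sorted(tied.index.tolist())
    change_rows = []
    for y0, y1 in periods:
        for america in grid.index:
            change_rows.append({"america_id": america, "year_from": y0, "year_to": y1,
                                "change": compute_change(grid, america, y0, y1)})
    return DisparityReport(
        gaps=pd.DataFrame(gap_rows),
        changes=pd.DataFrame(change_rows),
        ranks=pd.DataFrame(rank_cols),
        ties=ties,
    )
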