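"""Assignment of county × race/ethnicity units to the ten Americas.

Every combination of county and race/ethnicity belongs to exactly one of ten
mutually exclusive, collectively exhaustive groups ("Americas") defined by
race/ethnicity together with geography, metropolitan status, race-specific
county income per capita, and Black–White residential segregation:

1.  Asian (combined Asian and NHPI where NHPI < 30% of the Asian+NHPI population)
2.  Latino — other counties
3.  White (majority), Asian, and AIAN — other counties
4.  White — non-metropolitan, low-income Northlands
5.  Latino — Southwest
6.  Black — other counties
7.  Black — highly segregated, high-population metropolitan counties
8.  White — low-income Appalachia and Lower Mississippi Valley
9.  Black — non-metropolitan, low-income Lower Mississippi Valley / Deep South
10. AIAN — West (excluding the Pacific Coast)

"Low-income" means the county's race-specific income per capita is strictly
below $32,363, the median all-race county income per capita in 2020.
"Highly segregated" means a Black–White dissimilarity index of 60 or more.
Metropolitan status comes from USDA Rural–Urban Continuum Codes: code 1 is a
metro area of one million or more; codes 4–9 are non-metropolitan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CountyAttributes",
    "AmericaAssignment",
    "PartitionError",
    "AMERICA_LABELS",
    "RACES",
    "INCOME_THRESHOLD",
    "DISSIMILARITY_THRESHOLD",
    "SOUTHWEST_STATES",
    "WEST_STATES",
    "NORTHLANDS_STATES",
    "DEEP_SOUTH_STATES",
    "dissimilarity_index",
    "is_high_population_metropolitan",
    "is_nonmetropolitan",
    "is_low_income",
    "assign_america",
    "assign_americas",
    "validate_partition",
]

#: Canonical race/ethnicity labels. "Asian" is the combined Asian and NHPI
#: population (the two cannot be fully distinguished in deaths data before
#: 2011); all labels except "Latino" refer to the non-Latino population.
RACES: tuple[str, ...] = ("AIAN", "Asian", "Black", "Latino", "White")

AMERICA_LABELS: dict[int, str] = {
    1: "Asian",
    2: "Latino | Other counties",
    3: "White (majority), Asian, AIAN | Other counties",
    4: "White | Non-metropolitan and low-income Northlands",
    5: "Latino | Southwest",
    6: "Black | Other counties",
    7: "Black | Highly segregated metropolitan areas",
    8: "White | Low-income Appalachia and Lower Mississippi Valley",
    9: "Black | Non-metropolitan and low-income South",
    10: "AIAN | West",
}

#: Median all-race county income per capita in 2020 (USD); "low-income" is
#: strictly below this value.
INCOME_THRESHOLD: float = 32_363.0

#: Black–White dissimilarity index at or above which a county counts as
#: highly segregated.
DISSIMILARITY_THRESHOLD: float = 60.0

#: NHPI share of the combined Asian+NHPI population below which a county's
#: Asian population belongs to America 1.
NHPI_SHARE_THRESHOLD: float = 0.30

SOUTHWEST_STATES = frozenset({"AZ", "CO", "NM", "TX"})
WEST_STATES = frozenset(
    {"AZ", "CO", "ID", "KS", "MN", "MT", "NE", "NV", "NM", "ND", "OK", "SD", "UT", "WY"}
)
NORTHLANDS_STATES = frozenset({"IA", "MN", "MT", "NE", "ND", "SD"})
DEEP_SOUTH_STATES = frozenset({"SC", "GA", "AL", "MS", "LA"})

US_STATES: tuple[str, ...] = (
    "AL", "AK", "AZ", "AR", "CA", "CO", "CT", "DE", "FL", "GA",
    "HI", "ID", "IL", "IN", "IA", "KS", "KY", "LA", "ME", "MD",
    "MA", "MI", "MN", "MS", "MO", "MT", "NE", "NV", "NH", "NJ",
    "NM", "NY", "NC", "ND", "OH", "OK", "OR", "PA", "RI", "SC",
    "SD", "TN", "TX", "UT", "VT", "VA", "WA", "WV", "WI", "WY",
)

#: Census-region membership, used as a ratio-stratification dimension.
CENSUS_REGIONS: dict[str, str] = {
    **{s: "Northeast" for s in ("CT", "ME", "MA", "NH", "NJ", "NY", "PA", "RI", "VT")},
    **{s: "Midwest" for s in ("IL", "IN", "IA", "KS", "MI", "MN", "MO", "NE", "ND", "OH", "SD", "WI")},
    **{s: "South" for s in ("AL", "AR", "DE", "FL", "GA", "KY", "LA", "MD", "MS", "NC",
                            "OK", "SC", "TN", "TX", "VA", "WV")},
    **{s: "West" for s in ("AK", "AZ", "CA", "CO", "HI", "ID", "MT", "NV", "NM", "OR",
                           "UT", "WA", "WY")},
}


class PartitionError(ValueError):
    """The county×race units do not form a valid one-to-one partition."""


@dataclass(frozen=True)
class CountyAttributes:
    """Classification inputs for one county.

    ``income_per_capita_by_race`` holds 2020 income per capita (USD/person)
    keyed by race label; ``nhpi_share`` is the NHPI fraction of the combined
    Asian+NHPI population in 2020; ``dissimilarity_index`` is on the 0–100
    scale.
    """

    county_id: str
    state: str
    rucc: int
    income_per_capita_by_race: dict[str, float]
    dissimilarity_index: float
    nhpi_share: float
    appalachia: bool = False
    lower_mississippi_valley: bool = False
    deep_south: bool = False

    def __post_init__(self):
        if self.rucc not in range(1, 10):
            raise ValueError(f"RUCC must be 1-9, got {self.rucc}")
        if not 0 <= self.dissimilarity_index <= 100:
            raise ValueError("dissimilarity index must be in [0, 100]")
        if not 0 <= self.nhpi_share <= 1:
            raise ValueError("NHPI share must be in [0, 1]")
        for race, inc in self.income_per_capita_by_race.items():
            if inc <= 0:
                raise ValueError(f"income for {race} must be > 0")


@dataclass(frozen=True)
class AmericaAssignment:
    county_id: str
    race: str
    america_id: int


def dissimilarity_index(black_counts, white_counts) -> float:
    """Index of dissimilarity D = 50 · Σᵢ |bᵢ/B − wᵢ/W| over subunits i.

    0 means the two groups are identically distributed over subunits; 100
    means complete segregation. Raises if either group's total is zero.
    """
    b = np.asarray(black_counts, dtype=float)
    w = np.asarray(white_counts, dtype=float)
    if b.shape != w.shape or b.size == 0:
        raise ValueError("subunit count vectors must be non-empty and aligned")
    if (b < 0).any() or (w < 0).any():
        raise ValueError("subunit counts must be non-negative")
    B, W = b.sum(), w.sum()
    if B == 0 or W == 0:
        raise ValueError("dissimilarity index undefined: a group total is zero")
    return float(50.0 * np.abs(b / B - w / W).sum())


def is_high_population_metropolitan(attrs: CountyAttributes) -> bool:
    """RUCC 1: county in a metropolitan area of one million or more."""
    return attrs.rucc == 1


def is_nonmetropolitan(attrs: CountyAttributes) -> bool:
    """RUCC 4-9."""
    return 4 <= attrs.rucc <= 9


def is_low_income(attrs: CountyAttributes, race: str) -> bool:
    """Race-specific income per capita strictly below the all-race median."""
    try:
        income = attrs.income_per_capita_by_race[race]
    except KeyError:
        raise KeyError(f"no income recorded for race {race!r} in {attrs.county_id}") from None
    return income < INCOME_THRESHOLD


def assign_america(attrs: CountyAttributes, race: str) -> int:
    """America id (1-10) for one county × race unit.

    For Black units the highly-segregated-metropolitan rule (America 7) takes
    precedence over the non-metropolitan Southern rule (America 9); the two
    cannot both hold under valid attributes (RUCC 1 vs 4-9) but the ordering
    makes the map deterministic regardless.
    """
    if race == "Latino":
        return 5 if attrs.state in SOUTHWEST_STATES else 2
    if race == "Asian":
        return 1 if attrs.nhpi_share < NHPI_SHARE_THRESHOLD else 3
    if race == "AIAN":
        return 10 if attrs.state in WEST_STATES else 3
    if race == "Black":
        if is_high_population_metropolitan(attrs) and attrs.dissimilarity_index >= DISSIMILARITY_THRESHOLD:
            return 7
        if (
            is_nonmetropolitan(attrs)
            and (attrs.lower_mississippi_valley or attrs.deep_south)
            and is_low_income(attrs, "Black")
        ):
            return 9
        return 6
    if race == "White":
        if is_nonmetropolitan(attrs) and attrs.state in NORTHLANDS_STATES and is_low_income(attrs, "White"):
            return 4
        if (attrs.appalachia or attrs.lower_mississippi_valley) and is_low_income(attrs, "White"):
            return 8
        return 3
    raise ValueError(f"unknown race/ethnicity label {race!r}")


def _row_attrs(row: pd.Series) -> CountyAttributes:
    incomes = {r: row[f"income_{r}"] for r in RACES if f"income_{r}" in row.index}
    return CountyAttributes(
        county_id=row["county_id"],
        state=row["state"],
        rucc=int(row["rucc"]),
        income_per_capita_by_race=incomes,
        dissimilarity_index=row["dissimilarity_index"],
        nhpi_share=row["nhpi_share"],
        appalachia=bool(row["appalachia"]),
        lower_mississippi_valley=bool(row["lower_mississippi_valley"]),
        deep_south=bool(row["deep_south"]),
    )


def assign_americas(attributes: pd.DataFrame, races=RACES) -> pd.DataFrame:
    """Vectorised assignment for a county-attribute table.

    Expects columns ``county_id, state, rucc, dissimilarity_index,
    nhpi_share, appalachia, lower_mississippi_valley, deep_south`` plus
    ``income_<race>`` per race. Returns a frame with one row per
    (county_id, race) and an ``america_id`` column.
    """
    frames = []
    st = attributes["state"]
    rucc = attributes["rucc"].astype(int)
    nonmetro = rucc.between(4, 9)
    for race in races:
        if race == "Latino":
            ids = np.where(st.isin(SOUTHWEST_STATES), 5, 2)
        elif race == "Asian":
            ids = np.where(attributes["nhpi_share"] < NHPI_SHARE_THRESHOLD, 1, 3)
        elif race == "AIAN":
            ids = np.where(st.isin(WEST_STATES), 10, 3)
        elif race == "Black":
            low = attributes["income_Black"] < INCOME_THRESHOLD
            a7 = (rucc == 1) & (attributes["dissimilarity_index"] >= DISSIMILARITY_THRESHOLD)
            a9 = (
                nonmetro
                & (attributes["lower_mississippi_valley"] | attributes["deep_south"])
                & low
            )
            ids = np.select([a7, a9], [7, 9], default=6)
        elif race == "White":
            low = attributes["income_White"] < INCOME_THRESHOLD
            a4 = nonmetro & st.isin(NORTHLANDS_STATES) & low
            a8 = (attributes["appalachia"] | attributes["lower_mississippi_valley"]) & low
            ids = np.select([a4, a8], [4, 8], default=3)
        else:
            raise ValueError(f"unknown race/ethnicity label {race!r}")
        frames.append(
            pd.DataFrame(
                {"county_id": attributes["county_id"], "race": race, "america_id": ids}
            )
        )
    return pd.concat(frames, ignore_index=True)


def validate_partition(assignments: pd.DataFrame, units: pd.DataFrame | None = None,
                       require_all_americas: bool = False) -> pd.Series:
    """Check the assignment is a bijection onto the expected units.

    ``units`` is a frame with columns (county_id, race); when omitted the
    assignment's own keys are checked for duplicates only. Returns per-America
    unit counts. Raises :class:`PartitionError` naming offending units.
    """
    key = assignments[["county_id", "race"]]
    dupes = key[key.duplicated(keep=False)]
    if not dupes.empty:
        offenders = sorted(set(map(tuple, dupes.values)))
        raise PartitionError(f"units assigned more than once: {offenders[:10]}")
    if units is not None:
        want = set(map(tuple, units[["county_id", "race"]].values))
        have = set(map(tuple, key.values))
        missing = sorted(want - have)
        extra = sorted(have - want)
        if missing or extra:
            raise PartitionError(
                f"partition violation: missing={missing[:10]} extra={extra[:10]}"
            )
    counts = assignments["america_id"].value_counts().reindex(range(1, 11), fill_value=0)
    counts.index.name = "america_id"
    if require_all_americas:
        empty = counts[counts == 0].index.tolist()
        if empty:
            raise PartitionError(f"Americas with no county×race units: {empty}")
    return counts
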