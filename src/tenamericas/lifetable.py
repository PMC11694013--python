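"""Abridged life tables, partial life expectancy, and ensemble summaries.

Mortality rates m(x) by age group are converted to probabilities of dying
q(x) = n·m / (1 + (n − a)·m), survivorship l(x) from a radix of 100,000,
person-years L(x) = n·l(x+n) + a·d(x) for closed groups, and remaining life
expectancy e(x) = T(x)/l(x). The terminal (85+) group uses a pluggable
strategy for e(85): the reciprocal of the terminal death rate under a
constant hazard, or a growth-rate-adjusted variant for non-stationary
populations.

Average years lived by decedents, a(x), follows the common abridged
convention: a(0) = 0.07 + 1.7·m(0) for the infant group and a = n/2
elsewhere. Partial (temporary) life expectancy over [x1, x2) is
(T(x1) − T(x2))/l(x1), the mean years lived in the range by survivors to
x1, bounded above by the range width.

All column computations are vectorised over arbitrary leading axes, so a
whole (America × year × sex × simulation) block of schedules is processed
in one call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ages import AgeSchema, PARTIAL_LE_RANGES, default_abridged_schema

__all__ = [
    "RADIX",
    "AbridgedLifeTable",
    "EstimateEnsemble",
    "mortality_rates",
    "mx_to_qx",
    "terminal_ex",
    "build_life_table",
    "temporary_life_expectancy",
    "summarize_ensemble",
]

RADIX = 100_000.0

#: Sensitivity (years) of terminal life expectancy to the old-age population
#: growth rate in the growth-adjusted terminal strategy; see docs/methods.md.
TERMINAL_GROWTH_BETA = 5.5


def mortality_rates(deaths: pd.DataFrame, population: pd.DataFrame,
                    by=("america_id", "year", "age_group", "sex")) -> pd.DataFrame:
    """Pooled death rates m = Σdeaths / Σpopulation within each stratum.

    Counties and races are summed within each stratum before dividing, so
    the stratum rate is the pooled rate, not a mean of sub-rates. Zero
    population with nonzero deaths is an error; zero population with zero
    deaths yields rate 0 with a warning.
    """
    by = list(by)
    d = deaths.groupby(by, observed=True)["value"].sum()
    p = population.groupby(by, observed=True)["value"].sum()
    merged = pd.concat({"deaths": d, "population": p}, axis=1).fillna(0.0)
    bad = (merged["population"] <= 0) & (merged["deaths"] > 0)
    if bad.any():
        raise ValueError(
            f"zero population with nonzero deaths in strata {merged.index[bad].tolist()[:5]}"
        )
    empty = merged["population"] <= 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} strata with zero population; rate set to 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(empty, 0.0, merged["deaths"] / merged["population"])
    out = merged.reset_index()
    out["m"] = m
    return out[by + ["m"]]


def mx_to_qx(m, n, a, terminal=False):
    """Death probability q = n·m / (1 + (n − a)·m), capped at 1.

    The terminal group has q = 1 by convention (everyone alive at the start
    of the open interval dies in it).
    """
    m = np.asarray(m, dtype=float)
    if terminal:
        return np.ones_like(m)
    q = n * m / (1.0 + (n - a) * m)
    return np.clip(q, 0.0, 1.0)


def terminal_ex(m_terminal, strategy: str = "constant_hazard",
                growth_rate=0.0, beta: float = TERMINAL_GROWTH_BETA):
    """Remaining life expectancy in the open age group from its death rate.

    ``constant_hazard`` returns 1/m (stationary population, flat hazard).
    ``horiuchi_coale`` applies a first-order stable-population correction
    e = (1/m)·exp(−β·r) using the terminal-ages population growth rate r:
    in a growing old-age population the observed death rate under-weights
    the oldest ages, so 1/m overstates remaining life expectancy. Both are
    strictly decreasing in m, and the two coincide at r = 0.
    """
    m = np.asarray(m_terminal, dtype=float)
    if (m <= 0).any():
        raise ValueError("terminal death rate must be strictly positive")
    if strategy == "constant_hazard":
        return 1.0 / m
    if strategy == "horiuchi_coale":
        r = np.asarray(growth_rate, dtype=float)
        return (1.0 / m) * np.exp(-beta * r)
    raise ValueError(f"unknown terminal strategy {strategy!r}")


@dataclass(frozen=True)
class AbridgedLifeTable:
    """Full abridged life-table column set over one age schema.

    Arrays share a trailing age axis of length ``len(schema)``; leading axes
    (if any) index e.g. America × year × sex × simulation.
    """

    schema: AgeSchema
    m: np.ndarray
    a: np.ndarray
    q: np.ndarray
    l: np.ndarray
    d: np.ndarray
    L: np.ndarray
    T: np.ndarray
    e: np.ndarray

    @property
    def e0(self) -> np.ndarray:
        return self.e[..., 0]

    def to_frame(self) -> pd.DataFrame:
        """Single-schedule tables only: one row per age group."""
        if self.m.ndim != 1:
            raise ValueError("to_frame requires a single schedule (1-D columns)")
        return pd.DataFrame(
            {
                "age_group": self.schema.labels,
                "m": self.m, "a": self.a, "q": self.q, "l": self.l,
                "d": self.d, "L": self.L, "T": self.T, "e": self.e,
            }
        )


def build_life_table(m_schedule, schema: AgeSchema | None = None,
                     terminal_strategy: str = "constant_hazard",
                     growth_rate=0.0) -> AbridgedLifeTable:
    """Construct an abridged life table from an m schedule.

    ``m_schedule`` has the age groups on the last axis, matching ``schema``
    (default: the standard 0/1-4/5-year/85+ schema). ``growth_rate`` feeds
    the growth-adjusted terminal strategy and may broadcast against the
    leading axes.
    """
    schema = schema or default_abridged_schema()
    m = np.asarray(m_schedule, dtype=float)
    k = len(schema)
    if m.shape[-1] != k:
        raise ValueError(f"m schedule has {m.shape[-1]} age groups, schema has {k}")
    if (m < 0).any() or not np.isfinite(m).all():
        raise ValueError("death rates must be finite and non-negative")

    n = schema.widths  # terminal entry NaN
    a = np.empty_like(m)
    for i, g in enumerate(schema.groups):
        if g.is_terminal:
            continue
        a[..., i] = 0.07 + 1.7 * m[..., i] if g.start == 0 and g.width == 1 else g.width / 2.0

    q = np.empty_like(m)
    for i, g in enumerate(schema.groups):
        q[..., i] = mx_to_qx(m[..., i], None if g.is_terminal else n[i],
                             None if g.is_terminal else a[..., i], terminal=g.is_terminal)

    l = np.empty_like(m)
    d = np.empty_like(m)
    l[..., 0] = RADIX
    for i in range(k - 1):
        d[..., i] = l[..., i] * q[..., i]
        l[..., i + 1] = l[..., i] - d[..., i]
    d[..., k - 1] = l[..., k - 1]

    # terminal e(85): where no one survives to 85 the terminal rate may be 0;
    # the terminal person-years are then 0 regardless of e85.
    m_term = m[..., k - 1]
    safe_m = np.where(m_term > 0, m_term, 1.0)
    e_term = terminal_ex(safe_m, strategy=terminal_strategy, growth_rate=growth_rate)
    e_term = np.where(m_term > 0, e_term, 0.0)
    a[..., k - 1] = e_term

    L = np.empty_like(m)
    for i in range(k - 1):
        L[..., i] = n[i] * l[..., i + 1] + a[..., i] * d[..., i]
    L[..., k - 1] = l[..., k - 1] * e_term

    T = np.flip(np.cumsum(np.flip(L, axis=-1), axis=-1), axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l > 0, T / np.where(l > 0, l, 1.0), 0.0)
    return AbridgedLifeTable(schema=schema, m=m, a=a, q=q, l=l, d=d, L=L, T=T, e=e)


def temporary_life_expectancy(table: AbridgedLifeTable, x1: float, x2: float) -> np.ndarray:
    """Partial life expectancy over [x1, x2): (T(x1) − T(x2)) / l(x1).

    Both boundaries must lie on the schema and x2 must be finite (remaining
    life expectancy in the open group is a different quantity, available as
    ``table.e[..., -1]``).
    """
    if not x1 < x2:
        raise ValueError("require x1 < x2")
    i1 = table.schema.index_of_boundary(x1)
    if table.schema.groups[i1].is_terminal:
        raise ValueError(
            "partial life expectancy starting in the open terminal group is "
            "undefined; use remaining life expectancy e(85) instead"
        )
    i2 = table.schema.index_of_boundary(x2)
    l1 = table.l[..., i1]
    out = (table.T[..., i1] - table.T[..., i2]) / np.where(l1 > 0, l1, 1.0)
    return np.where(l1 > 0, out, 0.0)


@dataclass(frozen=True)
class EstimateEnsemble:
    """Simulation draws of one quantity with their point estimate and 95% UI.

    The point estimate is the draw mean; the uncertainty interval runs from
    the 2.5th to the 97.5th percentile of the draws (linear interpolation
    between order statistics).
    """

    label: str
    draws: np.ndarray
    mean: float
    lower: float
    upper: float


def summarize_ensemble(draws, label: str = "") -> EstimateEnsemble:
    draws = np.asarray(draws, dtype=float)
    if draws.size < 2:
        raise ValueError("need at least two simulation draws to summarise")
    lower, upper = np.percentile(draws, [2.5, 97.5], method="linear")
    return EstimateEnsemble(
        label=label,
        draws=draws,
        mean=float(draws.mean()),
        lower=float(lower),
        upper=float(upper),
    )


def life_expectancy_quantities(table: AbridgedLifeTable) -> dict[str, np.ndarray]:
    """e0, partial life expectancies for the five reporting ranges, and e85."""
    out = {"e0": table.e0}
    for x1, x2 in PARTIAL_LE_RANGES:
        out[f"ple_{x1}_{x2 - 1}"] = temporary_life_expectancy(table, x1, x2)
    out["e85"] = table.e[..., -1]
    return out
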