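"""Configuration for the synthetic vital-statistics generator.

The generator emulates the statistical structure of national vital
statistics: stratified death and population counts by year, county, age
group, sex and race/ethnicity; a race-misreporting process on death records;
a census-base discontinuity in the population series; and a "Two or More
Races" reported category requiring reallocation. Its defaults define the
study conditions the test suite exercises.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .classify import RACES

__all__ = ["GompertzMakeham", "SyntheticConfig", "ConfigurationError", "MULTIRACE_LABEL"]

#: Label of the reported "Two or More Races" category.
MULTIRACE_LABEL = "Multiple"


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class GompertzMakeham:
    """Gompertz–Makeham hazard h(x) = makeham + level · exp(slope · x)."""

    level: float
    slope: float
    makeham: float

    def __post_init__(self):
        if self.level <= 0 or self.slope <= 0 or self.makeham < 0:
            raise ConfigurationError("Gompertz-Makeham parameters must be positive")

    def hazard(self, age) -> np.ndarray:
        return self.makeham + self.level * np.exp(self.slope * np.asarray(age, dtype=float))


# Hazard levels calibrated once so that race-specific life expectancy at
# birth sits in a realistic band (AIAN lowest at ~71 y, Asian highest at
# ~83 y, female-male gap ~5 y); see docs/methods.md.
_DEFAULT_GOMPERTZ: dict[str, GompertzMakeham] = {
    "AIAN": GompertzMakeham(level=7.2436e-05, slope=0.0835, makeham=1.0348e-03),  # e0 ~ 71.0
    "Asian": GompertzMakeham(level=1.0870e-05, slope=0.1000, makeham=1.5528e-04),  # e0 ~ 83.0
    "Black": GompertzMakeham(level=5.0932e-05, slope=0.0880, makeham=8.0036e-04),  # e0 ~ 72.5
    "Latino": GompertzMakeham(level=1.7447e-05, slope=0.0960, makeham=2.4233e-04),  # e0 ~ 80.5
    "White": GompertzMakeham(level=2.6463e-05, slope=0.0930, makeham=4.0270e-04),  # e0 ~ 77.5
}

#: Multiplier applied to the level/makeham terms for males (female-male
#: mortality differential).
DEFAULT_MALE_EXCESS = 1.55

# Row-stochastic misreporting matrix P[true, recorded] over RACES order.
# Net misclassification on death certificates is strongest for AIAN
# decedents (recorded as White about a quarter of the time), moderate for
# Asian and Latino decedents, and near-diagonal for Black and White. The
# matrix is constant over age, sex and region; dependence of the net ratios
# on co-ethnic density arises mechanically from county composition.
_DEFAULT_MISREPORT = np.array(
    [
        # AIAN   Asian  Black  Latino White
        [0.750, 0.005, 0.005, 0.015, 0.225],  # true AIAN
        [0.002, 0.930, 0.003, 0.010, 0.055],  # true Asian
        [0.001, 0.001, 0.990, 0.003, 0.005],  # true Black
        [0.002, 0.003, 0.005, 0.950, 0.040],  # true Latino
        [0.001, 0.001, 0.002, 0.006, 0.990],  # true White
    ]
)

#: Fraction of each race's reported counts recorded as "Two or More Races"
#: in years at or after the census-base year.
_DEFAULT_MULTIRACE_FRACTIONS = {
    "AIAN": 0.15,
    "Asian": 0.05,
    "Black": 0.03,
    "Latino": 0.0,
    "White": 0.02,
}


@dataclass
class SyntheticConfig:
    """All generator parameters plus the master seed.

    ``years`` is an inclusive range. ``misreport_matrix`` rows must be
    non-negative and sum to one. ``discontinuity_scale`` is the relative
    size of the census-base level shift injected at ``discontinuity_year``.
    """

    n_counties: int = 200
    years: tuple[int, int] = (2000, 2021)
    age_schema_id: str = "abridged_0_85"
    races: tuple[str, ...] = RACES
    sex_labels: tuple[str, str] = ("female", "male")
    gompertz_params: dict[str, GompertzMakeham] = field(
        default_factory=lambda: dict(_DEFAULT_GOMPERTZ)
    )
    male_excess: float = DEFAULT_MALE_EXCESS
    misreport_matrix: np.ndarray = field(
        default_factory=lambda: _DEFAULT_MISREPORT.copy()
    )
    discontinuity_year: int = 2020
    discontinuity_scale: float = 0.03
    multirace_fractions: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MULTIRACE_FRACTIONS)
    )
    low_income_fraction: float = 0.5
    #: Delta-method stand-in for the external linkage-study SEs (see docs).
    ratio_se_method: str = "delta_poisson"
    seed: int = 0

    def __post_init__(self):
        self.misreport_matrix = np.asarray(self.misreport_matrix, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_counties < 10:
            raise ConfigurationError("n_counties must be at least 10")
        y0, y1 = self.years
        if y1 < y0:
            raise ConfigurationError("years range is inverted")
        m = self.misreport_matrix
        k = len(self.races)
        if m.shape != (k, k):
            raise ConfigurationError(f"misreport_matrix must be {k}x{k}")
        if (m < 0).any() or np.max(np.abs(m.sum(axis=1) - 1.0)) > 1e-12:
            raise ConfigurationError(
                "misreport_matrix rows must be non-negative and sum to 1"
            )
        for race in self.races:
            if race not in self.gompertz_params:
                raise ConfigurationError(f"no hazard parameters for race {race!r}")
            # strict positivity of the hazard at all ages follows from the
            # GompertzMakeham parameter constraints
        for race, frac in self.multirace_fractions.items():
            if not 0 <= frac < 1:
                raise ConfigurationError(f"multirace fraction for {race!r} must be in [0,1)")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    def hazard(self, race: str, sex: str, age) -> np.ndarray:
        """Sex-specific Gompertz–Makeham hazard for a race at given ages."""
        gp = self.gompertz_params[race]
        mult = self.male_excess if sex == "male" else 1.0
        return mult * gp.makeham + mult * gp.level * np.exp(gp.slope * np.asarray(age, float))

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["misreport_matrix"] = self.misreport_matrix.tolist()
        data["gompertz_params"] = {
            r: asdict(g) for r, g in self.gompertz_params.items()
        }
        data["races"] = list(self.races)
        data["sex_labels"] = list(self.sex_labels)
        data["years"] = list(self.years)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["years"] = tuple(data["years"])
        data["races"] = tuple(data["races"])
        data["sex_labels"] = tuple(data["sex_labels"])
        data["gompertz_params"] = {
            r: GompertzMakeham(**g) for r, g in data["gompertz_params"].items()
        }
        data["misreport_matrix"] = np.asarray(data["misreport_matrix"], dtype=float)
        return cls(**data)
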