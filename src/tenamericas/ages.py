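"""Abridged age schemas.

The default schema is the standard abridged grouping used throughout the
analysis: an infant group [0,1), a childhood group [1,5), 5-year groups up
to [80,85), and an open-ended terminal group 85+. Age-specific rates, life
tables and partial life expectancies all operate on this grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AgeGroup", "AgeSchema", "default_abridged_schema", "PARTIAL_LE_RANGES"]

#: Age ranges (closed-open, in years) for which partial life expectancy is reported.
PARTIAL_LE_RANGES: tuple[tuple[int, int], ...] = (
    (0, 5),
    (5, 25),
    (25, 45),
    (45, 65),
    (65, 85),
)


@dataclass(frozen=True)
class AgeGroup:
    """One age interval [start, end); ``end=None`` marks the open terminal group."""

    start: float
    end: float | None

    @property
    def is_terminal(self) -> bool:
        return self.end is None

    @property
    def width(self) -> float:
        if self.end is None:
            raise ValueError("terminal age group has no finite width")
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        # Terminal midpoint is a pragmatic hazard-evaluation point, not a width.
        if self.end is None:
            return self.start + 5.0
        return 0.5 * (self.start + self.end)

    @property
    def label(self) -> str:
        if self.end is None:
            return f"{int(self.start)}+"
        if self.width == 1:
            return f"{int(self.start)}"
        return f"{int(self.start)}-{int(self.end) - 1}"


@dataclass(frozen=True)
class AgeSchema:
    """Contiguous, non-overlapping abridged age grid starting at 0."""

    groups: tuple[AgeGroup, ...]
    schema_id: str = "abridged_0_85"
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if not self.groups:
            raise ValueError("empty age schema")
        if self.groups[0].start != 0:
            raise ValueError("age schema must start at age 0")
        for a, b in zip(self.groups[:-1], self.groups[1:]):
            if a.end != b.start:
                raise ValueError(f"age groups not contiguous at {a.label}/{b.label}")
        if not self.groups[-1].is_terminal:
            raise ValueError("age schema must end with an open terminal group")
        object.__setattr__(self, "_index", {g.label: i for i, g in enumerate(self.groups)})

    def __len__(self) -> int:
        return len(self.groups)

    @property
    def labels(self) -> list[str]:
        return [g.label for g in self.groups]

    @property
    def widths(self) -> np.ndarray:
        """Interval widths n; the terminal width is NaN (undefined)."""
        return np.array([g.width if not g.is_terminal else np.nan for g in self.groups])

    @property
    def starts(self) -> np.ndarray:
        return np.array([g.start for g in self.groups])

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([g.midpoint for g in self.groups])

    def index_of(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"age group {label!r} not in schema {self.schema_id!r}") from None

    def index_of_boundary(self, age: float) -> int:
        """Index of the group starting at ``age``; errors if off-schema."""
        for i, g in enumerate(self.groups):
            if g.start == age:
                return i
        raise ValueError(f"age {age} is not a boundary of schema {self.schema_id!r}")


def default_abridged_schema() -> AgeSchema:
    """0, 1-4, 5-9, ..., 80-84, 85+ (19 groups)."""
    bounds = [0, 1] + list(range(5, 90, 5))
    groups = [AgeGroup(s, e) for s, e in zip(bounds[:-1], bounds[1:])]
    groups.append(AgeGroup(85, None))
    return AgeSchema(tuple(groups))
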