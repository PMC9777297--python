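"""Descriptive arithmetic for the questionnaire screening phase.

The screening classifies 568 adolescents into no-alexithymia / some-symptoms
/ affected categories; only the counts and their reported percentages are in
scope here.  Two reporting conventions coexist in the source material:
one-decimal percentages rounded half-up, and a two-decimal affected rate
that is *truncated* (186/568 = 32.7465 reported as 32.74, not 32.75), so the
truncation mode is explicit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

CATEGORIES = ("no_alexithymia", "some_symptoms", "affected")


@dataclass(frozen=True)
class ScreeningTable:
    total: int
    category_counts: dict[str, int]
    sex_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("total must be positive")
        if any(c < 0 for c in self.category_counts.values()):
            raise ValueError("counts must be >= 0")
        if sum(self.category_counts.values()) != self.total:
            raise ValueError("category counts must sum to total")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScreeningTable":
        df = pd.read_csv(path)
        cats = dict(zip(df["category"], df["count"].astype(int)))
        sex = {k.removeprefix("sex_"): v for k, v in cats.items()
               if k.startswith("sex_")}
        cats = {k: v for k, v in cats.items() if not k.startswith("sex_")}
        return cls(total=sum(cats.values()), category_counts=cats, sex_counts=sex)


# Counts from the screening of 568 adolescents.
DEFAULT_SCREENING = ScreeningTable(
    total=568,
    category_counts={"no_alexithymia": 182, "some_symptoms": 200, "affected": 186},
    sex_counts={"female": 302, "male": 266},
)


def _round_half_up(x: float, decimals: int) -> float:
    factor = 10 ** decimals
    return math.floor(x * factor + 0.5) / factor


def _truncate(x: float, decimals: int) -> float:
    factor = 10 ** decimals
    return math.floor(x * factor) / factor


def percentage(count: int, total: int, decimals: int = 1,
               mode: str = "half_up") -> float:
    if total <= 0:
        raise ValueError("total must be positive")
    pct = 100.0 * count / total
    if mode == "half_up":
        return _round_half_up(pct, decimals)
    if mode == "truncate":
        return _truncate(pct, decimals)
    raise ValueError(f"unknown rounding mode {mode!r}")


def category_percentages(table: ScreeningTable, decimals: int = 1,
                         mode: str = "half_up") -> dict[str, float]:
    """Percent of the screened total per category (and per sex, if present)."""
    out = {name: percentage(count, table.total, decimals, mode)
           for name, count in table.category_counts.items()}
    out.update({f"sex_{name}": percentage(count, table.total, decimals, mode)
                for name, count in table.sex_counts.items()})
    return out


def affected_rate(table: ScreeningTable) -> float:
    """Affected share of the screened total, truncated to two decimals."""
    if "affected" not in table.category_counts:
        raise ValueError("table lacks an 'affected' category")
    return percentage(table.category_counts["affected"], table.total,
                      decimals=2, mode="truncate")
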