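"""Stimulus conditions: arrangements, numerosity ranges, and design covariates.

A stimulus condition is an (arrangement, numerosity) pair.  Three dot
arrangements are distinguished — ``random`` and ``canonical`` span
numerosities 2–8, ``dice`` spans 2–6 (the numerosities found on a cubic
die).  Numerosities up to 4 belong to the subitizing range, 5 and above to
the estimation range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .exceptions import ValidationError

ARRANGEMENTS = ("random", "canonical", "dice")

#: inclusive numerosity bounds per arrangement
NUMEROSITY_RANGE = {
    "random": (2, 8),
    "canonical": (2, 8),
    "dice": (2, 6),
}

#: largest set size still quantified by subitizing
SUBITIZING_MAX = 4

RANGES = ("subitizing", "estimation")


def number_range(numerosity: int) -> str:
    """Classify a numerosity as ``"subitizing"`` (<= 4) or ``"estimation"``."""
    return "subitizing" if numerosity <= SUBITIZING_MAX else "estimation"


def validate_condition(arrangement: str, numerosity: int) -> None:
    """Raise :class:`ValidationError` if the pair is not a valid condition."""
    if arrangement not in ARRANGEMENTS:
        raise ValidationError(
            f"unknown arrangement {arrangement!r}; expected one of {ARRANGEMENTS}"
        )
    lo, hi = NUMEROSITY_RANGE[arrangement]
    n = int(numerosity)
    if n != numerosity or not lo <= n <= hi:
        raise ValidationError(
            f"numerosity {numerosity!r} outside the valid range "
            f"[{lo}, {hi}] for arrangement {arrangement!r}"
        )


@dataclass(frozen=True, order=True)
class ConditionLabel:
    """One stimulus condition: a dot arrangement and a set size."""

    arrangement: str
    numerosity: int

    def __post_init__(self):
        validate_condition(self.arrangement, self.numerosity)

    @property
    def range(self) -> str:
        return number_range(self.numerosity)

    def __str__(self) -> str:  # e.g. "can2", "dice5"
        short = {"random": "rand", "canonical": "can", "dice": "dice"}
        return f"{short[self.arrangement]}{self.numerosity}"


def valid_conditions() -> list[ConditionLabel]:
    """All 19 conditions in canonical order (arrangement, then numerosity)."""
    out = []
    for arr in ARRANGEMENTS:
        lo, hi = NUMEROSITY_RANGE[arr]
        out.extend(ConditionLabel(arr, n) for n in range(lo, hi + 1))
    return out


def add_range_column(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of *df* with a ``range`` column derived from numerosity."""
    out = df.copy()
    out["range"] = out["numerosity"].map(number_range)
    return out


def center_numerosity(df: pd.DataFrame) -> pd.DataFrame:
    """Add a cell-centered numerosity covariate.

    Within every (arrangement x range) cell the covariate is
    ``numerosity - mean(numerosity)`` over the records of that cell, so each
    cell's centered mean is exactly zero.  A ``range`` column is added if
    absent.  Empty cells are skipped with a warning.

    Parameters
    ----------
    df : DataFrame with ``arrangement`` and ``numerosity`` columns.

    Returns
    -------
    DataFrame copy with added ``range`` and ``centered_n`` columns.
    """
    if df.empty:
        raise ValidationError("no records to center")
    bad = set(df["arrangement"].unique()) - set(ARRANGEMENTS)
    if bad:
        raise ValidationError(f"unknown arrangements in data: {sorted(bad)}")
    out = df if "range" in df.columns else add_range_column(df)
    out = out.copy()
    out["centered_n"] = out["numerosity"] - out.groupby(
        ["arrangement", "range"], observed=True
    )["numerosity"].transform("mean")
    # warn about design cells with no data (e.g. a subject without dice trials)
    present = set(map(tuple, out[["arrangement", "range"]].drop_duplicates().values))
    expected = {(a, r) for a in ARRANGEMENTS for r in RANGES}
    for cell in sorted(expected - present):
        warnings.warn(f"empty design cell skipped: {cell}", stacklevel=2)
    return out
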