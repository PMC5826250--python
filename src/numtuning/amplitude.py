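"""ROI amplitude analysis: percent-signal-change slopes and the
subitizing/estimation discontinuity.

Input is a tidy table of percent signal change (PSC) relative to fixation,
one row per subject x hemisphere x arrangement x numerosity.  The analysis
is a two-stage summary-statistics scheme: an ordinary least-squares slope of
PSC on cell-centered numerosity per subject and (arrangement x range) cell,
then group inference by mean/SE and sign-flip permutation.  Hemispheres are
pooled by default (a ``by_hemisphere`` flag splits them).

The signature result in this design is the discontinuity: flat PSC slopes
for set sizes up to four (subitizing) and a steep increase beyond
(estimation) — compared per subject by ``discontinuity_test``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conditions import center_numerosity, validate_condition
from .exceptions import InsufficientDataError, ValidationError
from .permutation import sign_flip_test

__all__ = [
    "PSC_COLUMNS",
    "validate_psc",
    "RangeSlopeModel",
    "RangeSlopeResults",
    "SlopeEstimate",
    "DiscontinuityResult",
    "range_slopes",
    "discontinuity_test",
    "range_amplitude_contrast",
    "psc_condition_table",
]

#: required columns of a PSC record table
PSC_COLUMNS = ("subject_id", "hemisphere", "arrangement", "numerosity", "psc")

HEMISPHERES = ("left", "right")


def validate_psc(df: pd.DataFrame) -> None:
    missing = [c for c in PSC_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"PSC table missing columns: {missing}")
    bad_hemi = set(df["hemisphere"].unique()) - set(HEMISPHERES)
    if bad_hemi:
        raise ValidationError(f"unknown hemisphere labels: {sorted(bad_hemi)}")
    for arr, n in df[["arrangement", "numerosity"]].drop_duplicates().values:
        validate_condition(arr, int(n))
    if not np.isfinite(df["psc"]).all():
        raise ValidationError("psc values must be finite")


@dataclass
class SlopeEstimate:
    """Group slope of a response on centered numerosity in one design cell."""

    arrangement: str
    range: str
    slope: float
    se: float
    n_subjects: int
    per_subject: dict[str, float] = field(default_factory=dict)
    n_omitted: int = 0
    hemisphere: str | None = None


@dataclass
class DiscontinuityResult:
    """Estimation-minus-subitizing slope difference with a sign-flip p."""

    arrangement: str
    delta_slope: float
    p_value: float
    n_permutations: int
    n_subjects: int


def _cell_slopes(df: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Per-(subject, arrangement, range) OLS slope of value on centered_n.

    Vectorized closed form: slope = S_xy / S_xx.  Cells where a subject has
    a single distinct numerosity (S_xx == 0) are dropped — the caller
    reports them as omitted.
    """
    g = df.groupby(["subject_id", "arrangement", "range"], observed=True)
    xm = g["centered_n"].transform("mean")
    ym = g[value_col].transform("mean")
    dx = df["centered_n"] - xm
    dy = df[value_col] - ym
    agg = pd.DataFrame(
        {"sxx": dx * dx, "sxy": dx * dy},
        index=df.index,
    ).groupby([df["subject_id"], df["arrangement"], df["range"]], observed=True).sum()
    agg = agg.rename_axis(["subject_id", "arrangement", "range"]).reset_index()
    agg["slope"] = np.where(agg["sxx"] > 0, agg["sxy"] / agg["sxx"], np.nan)
    return agg


class RangeSlopeModel:
    """Two-stage slope model of a response measure on centered numerosity.

    Stage one fits an OLS slope per subject within every
    (arrangement x range) cell; stage two summarizes slopes across subjects
    (mean, SE = sd/sqrt(n)) and supplies them to the permutation tests.
    Used both for PSC amplitudes and for log reaction times.
    """

    def __init__(self, data: pd.DataFrame, value_col: str = "psc",
                 pool_hemispheres: bool = True):
        if value_col == "psc":
            validate_psc(data)
        df = center_numerosity(data)
        self.value_col = value_col
        self.pool_hemispheres = pool_hemispheres
        self.data = df

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "RangeSlopeModel":
        return cls(data, **kwargs)

    def fit(self) -> "RangeSlopeResults":
        frames = []
        if self.pool_hemispheres or "hemisphere" not in self.data.columns:
            frames.append((None, _cell_slopes(self.data, self.value_col)))
        else:
            for hemi, sub in self.data.groupby("hemisphere", observed=True):
                frames.append((hemi, _cell_slopes(sub, self.value_col)))
        estimates = []
        for hemi, cells in frames:
            for (arr, rng_), grp in cells.groupby(["arrangement", "range"], observed=True):
                ok = grp.dropna(subset=["slope"])
                n_omitted = len(grp) - len(ok)
                n = len(ok)
                if n == 0:
                    continue
                slopes = ok["slope"].to_numpy()
                se = float(slopes.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
                estimates.append(
                    SlopeEstimate(
                        arrangement=arr,
                        range=rng_,
                        slope=float(slopes.mean()),
                        se=se,
                        n_subjects=n,
                        per_subject=dict(zip(ok["subject_id"], slopes)),
                        n_omitted=n_omitted,
                        hemisphere=hemi,
                    )
                )
        return RangeSlopeResults(estimates, value_col=self.value_col)


@dataclass
class RangeSlopeResults:
    """Collection of per-cell group slopes with summary and test methods."""

    estimates: list[SlopeEstimate]
    value_col: str = "psc"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.estimates:
            row = {
                "arrangement": e.arrangement,
                "range": e.range,
                "slope": e.slope,
                "se": e.se,
                "n_subjects": e.n_subjects,
                "n_omitted": e.n_omitted,
            }
            if e.hemisphere is not None:
                row["hemisphere"] = e.hemisphere
            rows.append(row)
        return pd.DataFrame(rows)

    def get(self, arrangement: str, range_: str,
            hemisphere: str | None = None) -> SlopeEstimate:
        for e in self.estimates:
            if (e.arrangement, e.range, e.hemisphere) == (arrangement, range_, hemisphere):
                return e
        raise KeyError((arrangement, range_, hemisphere))

    def summary(self) -> str:
        df = self.to_frame()
        lines = [f"Range slopes of {self.value_col} on centered numerosity",
                 "=" * 52,
                 df.to_string(index=False, float_format=lambda v: f"{v:8.4f}")]
        return "\n".join(lines)

    def discontinuity_test(self, arrangement: str, n_permutations: int = 10000,
                           seed: int = 0) -> DiscontinuityResult:
        """Sign-flip test of estimation-vs-subitizing slope difference.

        Pairs the per-subject slopes of the two ranges within
        ``arrangement`` (subjects present in both), takes their difference,
        and permutes its sign.
        """
        sub = self.get(arrangement, "subitizing")
        est = self.get(arrangement, "estimation")
        common = sorted(set(sub.per_subject) & set(est.per_subject))
        if len(common) < 3:
            raise InsufficientDataError(
                f"discontinuity test needs >= 3 matched subjects, got {len(common)}"
            )
        diffs = np.array(
            [est.per_subject[s] - sub.per_subject[s] for s in common]
        )
        delta, p = sign_flip_test(diffs, n_permutations=n_permutations, seed=seed)
        return DiscontinuityResult(
            arrangement=arrangement,
            delta_slope=delta,
            p_value=p,
            n_permutations=n_permutations,
            n_subjects=len(common),
        )


def range_slopes(records: pd.DataFrame, value_col: str = "psc",
                 pool_hemispheres: bool = True) -> RangeSlopeResults:
    """Per-subject OLS slopes pooled to group level (see RangeSlopeModel)."""
    return RangeSlopeModel(
        records, value_col=value_col, pool_hemispheres=pool_hemispheres
    ).fit()


def discontinuity_test(records_or_results, arrangement: str,
                       n_permutations: int = 10000, seed: int = 0,
                       value_col: str = "psc") -> DiscontinuityResult:
    """Estimation-minus-subitizing slope discontinuity for one arrangement.

    Accepts either a PSC record table or an already-fitted
    :class:`RangeSlopeResults`.
    """
    if isinstance(records_or_results, RangeSlopeResults):
        results = records_or_results
    else:
        results = range_slopes(records_or_results, value_col=value_col)
    return results.discontinuity_test(
        arrangement, n_permutations=n_permutations, seed=seed
    )


def range_amplitude_contrast(records: pd.DataFrame, n_permutations: int = 10000,
                             seed: int = 0, value_col: str = "psc") -> pd.DataFrame:
    """Mean response difference between ranges per arrangement, with
    sign-flip p-values.

    For each subject and arrangement the cell-mean response (over
    numerosities and hemispheres) is computed in both ranges; the
    estimation-minus-subitizing differences enter a sign-flip permutation
    test.  Returns one row per arrangement.
    """
    if value_col == "psc":
        validate_psc(records)
    df = center_numerosity(records)
    cell = (
        df.groupby(["subject_id", "arrangement", "range"], observed=True)[value_col]
        .mean()
        .unstack("range")
    )
    rows = []
    for k, (arr, grp) in enumerate(cell.groupby(level="arrangement", observed=True)):
        paired = grp.dropna(subset=["subitizing", "estimation"])
        diffs = (paired["estimation"] - paired["subitizing"]).to_numpy()
        delta, p = sign_flip_test(
            diffs, n_permutations=n_permutations,
            seed=int(np.random.SeedSequence([int(seed), k]).generate_state(1)[0] % 2**31),
        )
        rows.append(
            {
                "arrangement": arr,
                "delta_psc": delta,
                "p_value": p,
                "n_subjects": len(paired),
                "n_permutations": n_permutations,
            }
        )
    return pd.DataFrame(rows)


def psc_condition_table(records: pd.DataFrame) -> pd.DataFrame:
    """Descriptive table of PSC by arrangement x range x hemisphere.

    Mean, SD, minimum and maximum of the per-subject condition means —
    the layout of the classic ROI descriptives table.
    """
    validate_psc(records)
    df = center_numerosity(records)
    subj_means = (
        df.groupby(
            ["arrangement", "range", "hemisphere", "subject_id"], observed=True
        )["psc"].mean().reset_index()
    )
    out = (
        subj_means.groupby(["arrangement", "range", "hemisphere"], observed=True)["psc"]
        .agg(mean="mean", sd="std", min="min", max="max")
        .reset_index()
    )
    return out
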