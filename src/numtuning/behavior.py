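"""Behavioral trial processing: RT trimming, link-scale summaries, slopes.

Trials are rows of a tidy table (subject_id, arrangement, numerosity,
rt_ms, correct, run).  Reaction times are analyzed on the log scale
(right-skewed raw RTs), error rates on the log-odds scale; the printed
summaries back-transform with ``exp`` and the inverse logit respectively,
so an RT summary is a geometric mean and an ER summary a pooled proportion.

Trimming follows the standard two-step scheme: an absolute floor (drop
responses faster than 200 ms — anticipations, not quantifications) and a
model-based step that removes log RTs whose residuals from a per-subject
design fit (cell intercepts plus a centered-numerosity slope) exceed
+-3 SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .amplitude import RangeSlopeResults, range_slopes
from .conditions import ARRANGEMENTS, RANGES, center_numerosity, validate_condition
from .exceptions import ValidationError

__all__ = [
    "TRIAL_COLUMNS",
    "validate_trials",
    "TrimReport",
    "trim_rts",
    "logit_to_percent",
    "logmean_to_ms",
    "condition_summaries",
    "behavioral_slopes",
]

#: required columns of a trial table (``run`` is carried along if present)
TRIAL_COLUMNS = ("subject_id", "arrangement", "numerosity", "rt_ms", "correct")


def validate_trials(df: pd.DataFrame) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"trial table missing columns: {missing}")
    if df.empty:
        raise ValidationError("trial table is empty")
    if (df["rt_ms"] <= 0).any():
        raise ValidationError("reaction times must be > 0 ms")
    for arr, n in df[["arrangement", "numerosity"]].drop_duplicates().values:
        validate_condition(arr, int(n))


@dataclass
class TrimReport:
    """Bookkeeping of the trimming pipeline (counts always reconcile:
    n_input = n_retained + n_removed_error + n_removed_fast + n_removed_residual)."""

    n_input: int
    n_removed_error: int
    n_removed_fast: int
    n_removed_residual: int
    n_retained: int
    fraction_removed: float
    flagged_subjects: list[str] = field(default_factory=list)


def _design_residuals(df: pd.DataFrame) -> np.ndarray:
    """Residual log RT from per-subject fixed-effect fits.

    Per subject: one intercept per (arrangement x range) cell plus a common
    slope on cell-centered numerosity, solved by least squares.
    """
    resid = np.empty(len(df))
    cells = df["arrangement"].astype(str) + ":" + df["range"].astype(str)
    for _, idx in df.groupby("subject_id", observed=True).groups.items():
        sub = df.loc[idx]
        dummies = pd.get_dummies(cells.loc[idx], dtype=float)
        X = np.column_stack([dummies.to_numpy(), sub["centered_n"].to_numpy()])
        y = sub["log_rt"].to_numpy()
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid[df.index.get_indexer(idx)] = y - X @ beta
    return resid


def trim_rts(
    trials: pd.DataFrame,
    min_rt_ms: float = 200.0,
    z_threshold: float = 3.0,
    min_retained_per_subject: int = 5,
) -> tuple[pd.DataFrame, TrimReport]:
    """Trim a trial table for RT analysis.

    Pipeline (in order): drop error trials, drop RTs below ``min_rt_ms``,
    log-transform, compute residuals from per-subject design fits,
    standardize residuals globally, drop |z| > ``z_threshold``; the
    residual step repeats until no further trial is removed, which makes
    the whole procedure idempotent.

    Subjects left with fewer than ``min_retained_per_subject`` trials are
    flagged in the report but kept.  Retained rows are a subset of the
    input with added ``range``, ``centered_n``, ``log_rt`` and ``resid_z``
    columns.

    Returns
    -------
    (retained, TrimReport)
    """
    validate_trials(trials)
    n_input = len(trials)
    correct = trials[trials["correct"].astype(bool)]
    n_err = n_input - len(correct)
    kept = correct[correct["rt_ms"] >= min_rt_ms]
    n_fast = len(correct) - len(kept)
    if kept.empty:
        raise ValidationError("no trials survive the error/fast-RT filters")
    kept = center_numerosity(kept)
    kept["log_rt"] = np.log(kept["rt_ms"])
    # the residual step is iterated to its fixed point: removing an outlier
    # shrinks the residual SD, which can push further trials past the
    # threshold, so a single pass would not be idempotent
    retained = kept
    n_resid = 0
    for _ in range(50):
        resid = _design_residuals(retained)
        sd = resid.std()
        z = (resid - resid.mean()) / sd if sd > 0 else np.zeros_like(resid)
        retained = retained.assign(resid_z=z)
        survivors = retained[np.abs(retained["resid_z"]) <= z_threshold]
        dropped = len(retained) - len(survivors)
        retained = survivors
        if dropped == 0:
            break
        n_resid += dropped
    counts = retained["subject_id"].value_counts()
    flagged = sorted(
        set(trials["subject_id"].unique())
        - set(counts[counts >= min_retained_per_subject].index)
    )
    report = TrimReport(
        n_input=n_input,
        n_removed_error=n_err,
        n_removed_fast=n_fast,
        n_removed_residual=n_resid,
        n_retained=len(retained),
        fraction_removed=(n_input - len(retained)) / n_input,
        flagged_subjects=[str(s) for s in flagged],
    )
    return retained, report


def logit_to_percent(log_odds: float):
    """Back-transform a log-odds value to a percentage in (0, 100).

    ``100 / (1 + exp(-log_odds))``; strictly increasing, saturating
    gracefully at the extremes.
    """
    return 100.0 * expit(np.asarray(log_odds, dtype=float))[()]


def logmean_to_ms(log_rt: float):
    """Back-transform a mean log RT (log-ms) to milliseconds: ``exp(log_rt)``.

    Because the mean is taken on the log scale this is the geometric mean RT.
    """
    return np.exp(np.asarray(log_rt, dtype=float))[()]


def condition_summaries(
    trials: pd.DataFrame, retained: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-(arrangement x range) log-RT means and pooled error log-odds.

    Error rates must be computed before error trials are trimmed away, so
    this function takes the *full* trial table; pass the output of
    :func:`trim_rts` as ``retained`` to compute the log-RT means on trimmed
    correct trials only (otherwise all correct trials are used).

    Zero-error (or all-error) cells get a 0.5-count continuity correction,
    ``odds = (errors + 0.5) / (correct + 0.5)``, keeping the log-odds
    finite.  Cells without any trials are returned with NaN summaries.

    Returns a DataFrame with columns: arrangement, range, n_trials,
    n_errors, er_log_odds, er_backtransformed_percent, log_rt_mean,
    rt_backtransformed_ms.
    """
    validate_trials(trials)
    all_df = center_numerosity(trials)
    if retained is None:
        rt_df = all_df[all_df["correct"].astype(bool)].copy()
        rt_df["log_rt"] = np.log(rt_df["rt_ms"])
    else:
        rt_df = retained
    rows = []
    for arr in ARRANGEMENTS:
        for rng_ in RANGES:
            cell = all_df[(all_df["arrangement"] == arr) & (all_df["range"] == rng_)]
            if cell.empty:
                rows.append(
                    {"arrangement": arr, "range": rng_, "n_trials": 0,
                     "n_errors": 0, "er_log_odds": np.nan,
                     "er_backtransformed_percent": np.nan,
                     "log_rt_mean": np.nan, "rt_backtransformed_ms": np.nan}
                )
                continue
            n = len(cell)
            n_err = int((~cell["correct"].astype(bool)).sum())
            n_corr = n - n_err
            if n_err == 0 or n_corr == 0:
                odds = (n_err + 0.5) / (n_corr + 0.5)
            else:
                odds = n_err / n_corr
            log_odds = float(np.log(odds))
            rt_cell = rt_df[(rt_df["arrangement"] == arr) & (rt_df["range"] == rng_)]
            log_rt_mean = float(rt_cell["log_rt"].mean()) if len(rt_cell) else np.nan
            rows.append(
                {
                    "arrangement": arr,
                    "range": rng_,
                    "n_trials": n,
                    "n_errors": n_err,
                    "er_log_odds": log_odds,
                    "er_backtransformed_percent": float(logit_to_percent(log_odds)),
                    "log_rt_mean": log_rt_mean,
                    "rt_backtransformed_ms": float(logmean_to_ms(log_rt_mean))
                    if np.isfinite(log_rt_mean) else np.nan,
                }
            )
    return pd.DataFrame(rows)


def behavioral_slopes(trials: pd.DataFrame) -> RangeSlopeResults:
    """Group slopes of log RT on centered numerosity per (arrangement x range).

    Same two-stage contract as the amplitude slope analysis, applied to the
    log RT of correct trials.  Accepts either a raw trial table or the
    retained output of :func:`trim_rts` (recognized by its ``log_rt``
    column).
    """
    if "log_rt" not in trials.columns:
        validate_trials(trials)
        trials = trials[trials["correct"].astype(bool)].copy()
        trials["log_rt"] = np.log(trials["rt_ms"])
    return range_slopes(trials, value_col="log_rt")
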