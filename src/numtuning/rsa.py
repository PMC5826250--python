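"""Pairwise-decoding representational similarity analysis on voxel patterns.

Every unordered pair of stimulus conditions is decoded with a
cross-validated, ridge-penalized logistic regression on the subject's voxel
patterns.  Classification *error* (1 - accuracy) serves as the similarity
measure: conditions whose patterns a classifier cannot tell apart are
represented similarly.  Averaging the error over subjects yields a
condition x condition similarity matrix; its within-arrangement slices form
the similarity curves whose width the Gaussian tuning model estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .conditions import ConditionLabel
from .exceptions import ValidationError
from .tuning import NumerosityCurve, TuningFit, fit_tuning_width

__all__ = [
    "PatternSet",
    "SimilarityMatrix",
    "pairwise_decode",
    "similarity_matrix",
    "similarity_curves",
    "estimate_arrangement_width",
]


@dataclass
class PatternSet:
    """Voxel-pattern exemplars of one subject in one condition.

    ``patterns`` has shape (exemplars, voxels); at least two exemplars are
    required so cross-validation is possible, and the voxel count must match
    across all PatternSets of a subject.
    """

    subject_id: str
    condition: ConditionLabel
    patterns: np.ndarray

    def __post_init__(self):
        self.patterns = np.asarray(self.patterns, dtype=float)
        if self.patterns.ndim != 2:
            raise ValidationError("patterns must be a 2-D (exemplars x voxels) array")
        if self.patterns.shape[0] < 2:
            raise ValidationError("need >= 2 exemplars per condition")
        if not np.isfinite(self.patterns).all():
            raise ValidationError("patterns contain non-finite values")

    @property
    def n_exemplars(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.patterns.shape[1]


def pairwise_decode(
    a: PatternSet,
    b: PatternSet,
    n_folds: int = 5,
    penalty: float = 1.0,
    seed: int = 0,
) -> float:
    """Cross-validated two-class decoding accuracy between two conditions.

    A ridge-penalized logistic regression (L2 strength ``penalty``) on
    standardized voxel features, scored by stratified k-fold
    cross-validation; the scaler is fitted on training folds only.  Folds are
    reduced to the smaller class size when exemplars are scarce.
    Deterministic given ``seed``.

    Returns the mean accuracy over folds, in [0, 1].
    """
    if a.subject_id != b.subject_id:
        raise ValidationError(
            f"cannot decode across subjects ({a.subject_id!r} vs {b.subject_id!r})"
        )
    if a.condition == b.condition:
        raise ValidationError(f"invalid pair: both sets are condition {a.condition}")
    if a.n_voxels != b.n_voxels:
        raise ValidationError(
            f"voxel count mismatch: {a.n_voxels} vs {b.n_voxels}"
        )
    X = np.vstack([a.patterns, b.patterns])
    y = np.concatenate([np.zeros(a.n_exemplars), np.ones(b.n_exemplars)])
    folds = int(min(n_folds, a.n_exemplars, b.n_exemplars))
    if folds < 2:
        raise ValidationError("need >= 2 exemplars per class for cross-validation")
    clf = make_pipeline(
        StandardScaler(),
        LogisticRegression(C=1.0 / penalty, solver="lbfgs", max_iter=1000),
    )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed))
    scores = cross_val_score(clf, X, y, cv=cv, scoring="accuracy")
    return float(scores.mean())


@dataclass
class SimilarityMatrix:
    """Group-level classification-error similarity structure.

    ``errors[i, j]`` is the mean over subjects of 1 - decoding accuracy for
    conditions i and j; the diagonal is NaN (a condition cannot be decoded
    against itself).  ``per_subject`` stacks the subject-level matrices in
    the same condition order.
    """

    conditions: list[ConditionLabel]
    errors: np.ndarray
    per_subject: np.ndarray | None = None
    n_subjects: int = 0

    def __post_init__(self):
        self.errors = np.asarray(self.errors, dtype=float)
        k = len(self.conditions)
        if self.errors.shape != (k, k):
            raise ValidationError("errors must be square in the condition count")
        off = ~np.eye(k, dtype=bool) & ~np.isnan(self.errors)
        if not np.allclose(self.errors, self.errors.T, equal_nan=True):
            raise ValidationError("error matrix must be symmetric")
        vals = self.errors[off]
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValidationError("off-diagonal errors must lie in [0, 1]")

    def index_of(self, condition: ConditionLabel) -> int:
        return self.conditions.index(condition)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per computed unordered condition pair."""
        rows = []
        k = len(self.conditions)
        for i in range(k):
            for j in range(i + 1, k):
                if np.isnan(self.errors[i, j]):
                    continue
                ci, cj = self.conditions[i], self.conditions[j]
                rows.append(
                    {
                        "arrangement_a": ci.arrangement,
                        "n_a": ci.numerosity,
                        "arrangement_b": cj.arrangement,
                        "n_b": cj.numerosity,
                        "error": self.errors[i, j],
                        "n_subjects": self.n_subjects,
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SimilarityMatrix":
        """Rebuild a (possibly within-arrangement-only) matrix from
        :meth:`to_frame` output."""
        conds = sorted(
            {
                ConditionLabel(r["arrangement_a"], int(r["n_a"]))
                for _, r in df.iterrows()
            }
            | {
                ConditionLabel(r["arrangement_b"], int(r["n_b"]))
                for _, r in df.iterrows()
            },
            key=lambda c: (("random", "canonical", "dice").index(c.arrangement), c.numerosity),
        )
        k = len(conds)
        errors = np.full((k, k), np.nan)
        idx = {c: i for i, c in enumerate(conds)}
        for _, r in df.iterrows():
            i = idx[ConditionLabel(r["arrangement_a"], int(r["n_a"]))]
            j = idx[ConditionLabel(r["arrangement_b"], int(r["n_b"]))]
            errors[i, j] = errors[j, i] = float(r["error"])
        n_subj = int(df["n_subjects"].iloc[0]) if "n_subjects" in df and len(df) else 0
        return cls(conditions=conds, errors=errors, n_subjects=n_subj)


def _pair_seed(seed: int, subject_index: int, i: int, j: int) -> int:
    """Deterministic per-(subject, pair) CV seed derived from the master seed."""
    ss = np.random.SeedSequence([int(seed), subject_index, i, j])
    return int(ss.generate_state(1)[0] % (2**31))


def similarity_matrix(
    pattern_sets,
    n_folds: int = 5,
    penalty: float = 1.0,
    seed: int = 0,
    pairs: str = "all",
) -> SimilarityMatrix:
    """Decode every condition pair within each subject and average the errors.

    Parameters
    ----------
    pattern_sets : iterable of PatternSet
        All subjects; every subject must supply the identical condition set.
    pairs : {"all", "within"}
        ``"all"`` decodes cross-arrangement pairs too (e.g. can2 vs dice5);
        ``"within"`` restricts to same-arrangement pairs — sufficient for
        similarity-curve fitting and much cheaper.

    Returns
    -------
    SimilarityMatrix
        Group error matrix (mean over subjects), subject matrices retained.
    """
    if pairs not in ("all", "within"):
        raise ValidationError(f"pairs must be 'all' or 'within', got {pairs!r}")
    by_subject: dict[str, dict[ConditionLabel, PatternSet]] = {}
    for ps in pattern_sets:
        by_subject.setdefault(ps.subject_id, {})[ps.condition] = ps
    if not by_subject:
        raise ValidationError("no pattern sets supplied")
    subjects = sorted(by_subject)
    cond_sets = {s: frozenset(by_subject[s]) for s in subjects}
    reference = cond_sets[subjects[0]]
    offenders = [s for s in subjects if cond_sets[s] != reference]
    if offenders:
        raise ValidationError(
            f"subjects with inconsistent condition sets: {offenders}"
        )
    conditions = sorted(
        reference,
        key=lambda c: (("random", "canonical", "dice").index(c.arrangement), c.numerosity),
    )
    k = len(conditions)
    per_subject = np.full((len(subjects), k, k), np.nan)
    for si, s in enumerate(subjects):
        sets = by_subject[s]
        for i in range(k):
            for j in range(i + 1, k):
                ci, cj = conditions[i], conditions[j]
                if pairs == "within" and ci.arrangement != cj.arrangement:
                    continue
                acc = pairwise_decode(
                    sets[ci], sets[cj], n_folds=n_folds, penalty=penalty,
                    seed=_pair_seed(seed, si, i, j),
                )
                per_subject[si, i, j] = per_subject[si, j, i] = 1.0 - acc
    with np.errstate(invalid="ignore"):
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            errors = np.nanmean(per_subject, axis=0)
    np.fill_diagonal(errors, np.nan)
    return SimilarityMatrix(
        conditions=conditions,
        errors=errors,
        per_subject=per_subject,
        n_subjects=len(subjects),
    )


def similarity_curves(m: SimilarityMatrix, arrangement: str) -> list[NumerosityCurve]:
    """Within-arrangement similarity curves of a group matrix.

    One curve per reference numerosity; its values are the classification
    errors against every other numerosity of the same arrangement (the
    undefined self pair is omitted).
    """
    cond_idx = [
        (c, m.index_of(c)) for c in m.conditions if c.arrangement == arrangement
    ]
    if not cond_idx:
        raise KeyError(f"arrangement {arrangement!r} not present in matrix")
    curves = []
    for ref, i in cond_idx:
        probes, values = [], []
        for probe, j in cond_idx:
            if probe.numerosity == ref.numerosity:
                continue
            probes.append(probe.numerosity)
            values.append(float(np.clip(m.errors[i, j], 0.0, 1.0)))
        curves.append(NumerosityCurve(ref.numerosity, probes, values))
    return curves


def estimate_arrangement_width(
    m: SimilarityMatrix,
    arrangement: str,
    start_w: float = 0.4,
    fit_scale: bool = True,
) -> TuningFit:
    """Fit one tuning width to all similarity curves of an arrangement."""
    fit = fit_tuning_width(
        similarity_curves(m, arrangement), start_w=start_w, fit_scale=fit_scale
    )
    fit.arrangement = arrangement
    return fit
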