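"""Seeded synthetic-data generators for the three data modalities.

The generators emulate the statistical structure the analyses assume, with
defaults calibrated to the published group-level values of the study design
they stand in for:

* **Voxel patterns** — each simulated voxel has a preferred numerosity
  (log-uniform on [1, 10]) and responds to a stimulus of numerosity ``n``
  with the Gaussian tuning density of width ``w_arr * preferred`` (scalar
  variability), plus i.i.d. Gaussian noise.  Narrow widths (dice) produce
  tall, selective, decodable responses; wide widths (random) produce flat,
  confusable ones.
* **PSC records** — cell means/SDs per arrangement x range x hemisphere
  plus linear numerosity slopes per cell, a subject random intercept, and
  Gaussian residuals.
* **Behavioral trials** — 336 trials per subject balanced over the 19
  conditions; correctness Bernoulli from cell log-odds, RTs log-normal
  around cell log-means with numerosity slopes, and a small fraction of
  fast-guess contaminant trials (< 200 ms) so the trimming path is
  exercised.

Everything is deterministic given (config, seed); ground truth is retained
for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .conditions import (
    ARRANGEMENTS,
    NUMEROSITY_RANGE,
    RANGES,
    number_range,
    valid_conditions,
    ConditionLabel,
)
from .exceptions import SchemaError, ValidationError
from .rsa import PatternSet

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "sample_voxel_tuning",
    "generate_patterns",
    "generate_psc",
    "generate_behavior",
    "simulate_dataset",
]


def _default_widths():
    return {"random": 0.276, "canonical": 0.241, "dice": 0.094}


def _default_psc_cell_means():
    # (mean, sd) per arrangement -> range -> hemisphere
    return {
        "random": {
            "subitizing": {"left": (0.24, 0.15), "right": (0.14, 0.17)},
            "estimation": {"left": (0.42, 0.17), "right": (0.33, 0.23)},
        },
        "canonical": {
            "subitizing": {"left": (0.23, 0.16), "right": (0.12, 0.18)},
            "estimation": {"left": (0.38, 0.17), "right": (0.28, 0.22)},
        },
        "dice": {
            "subitizing": {"left": (0.28, 0.25), "right": (0.16, 0.24)},
            "estimation": {"left": (0.32, 0.23), "right": (0.19, 0.28)},
        },
    }


def _default_psc_slopes():
    return {
        "random": {"subitizing": -0.02, "estimation": 0.04},
        "canonical": {"subitizing": 0.00, "estimation": 0.00},
        "dice": {"subitizing": 0.01, "estimation": -0.14},
    }


def _default_rt_log_means():
    return {
        "random": {"subitizing": 6.27, "estimation": 6.82},
        "canonical": {"subitizing": 6.23, "estimation": 6.47},
        "dice": {"subitizing": 6.23, "estimation": 6.27},
    }


def _default_rt_slopes():
    return {
        "random": {"subitizing": 0.045, "estimation": 0.155},
        "canonical": {"subitizing": 0.041, "estimation": 0.010},
        "dice": {"subitizing": 0.004, "estimation": -0.021},
    }


def _default_er_log_odds():
    return {
        "random": {"subitizing": -5.51, "estimation": -1.46},
        "canonical": {"subitizing": -5.44, "estimation": -3.38},
        "dice": {"subitizing": -6.35, "estimation": -5.94},
    }


@dataclass
class GeneratorConfig:
    """All tunable parameters of the synthetic generators.

    Calibration maps (PSC cell means/SDs and slopes, log-RT means and
    slopes, error log-odds) default to the published group estimates; the
    purely mechanistic parameters (voxel count, gain, noise, subject SDs)
    are free choices documented in the methods note.
    """

    n_subjects: int = 24
    n_voxels: int = 200
    exemplars_per_condition: int = 12
    widths: dict = field(default_factory=_default_widths)
    pattern_gain: float = 1.0
    pattern_noise_sd: float = 0.7
    psc_cell_means: dict = field(default_factory=_default_psc_cell_means)
    psc_slopes: dict = field(default_factory=_default_psc_slopes)
    psc_subject_sd: float = 0.08
    rt_log_means: dict = field(default_factory=_default_rt_log_means)
    rt_slopes: dict = field(default_factory=_default_rt_slopes)
    rt_noise_sd: float = 0.25
    rt_subject_sd: float = 0.12
    er_log_odds: dict = field(default_factory=_default_er_log_odds)
    er_subject_sd: float = 0.3
    trials_per_subject: int = 336
    fast_guess_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name in ("pattern_noise_sd", "psc_subject_sd", "rt_noise_sd",
                     "rt_subject_sd", "er_subject_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.pattern_gain <= 0:
            raise ValidationError("pattern_gain must be > 0")
        if not 0 <= self.fast_guess_rate < 1:
            raise ValidationError("fast_guess_rate must be in [0, 1)")
        if set(self.widths) != set(ARRANGEMENTS):
            raise ValidationError(
                f"widths must have exactly the keys {ARRANGEMENTS}"
            )
        for arr, w in self.widths.items():
            if w <= 0:
                raise ValidationError(f"width for {arr!r} must be > 0")
        for name in ("psc_slopes", "rt_log_means", "rt_slopes", "er_log_odds"):
            m = getattr(self, name)
            if set(m) != set(ARRANGEMENTS):
                raise ValidationError(f"{name} must be keyed by {ARRANGEMENTS}")
            for arr in ARRANGEMENTS:
                if set(m[arr]) != set(RANGES):
                    raise ValidationError(
                        f"{name}[{arr!r}] must be keyed by {RANGES}"
                    )
        for arr in ARRANGEMENTS:
            for rng_ in RANGES:
                cell = self.psc_cell_means[arr][rng_]
                for hemi in ("left", "right"):
                    mean, sd = cell[hemi]
                    if sd < 0:
                        raise ValidationError(
                            f"psc SD for ({arr}, {rng_}, {hemi}) must be >= 0"
                        )
        if self.n_subjects < 1 or self.n_voxels < 1:
            raise ValidationError("n_subjects and n_voxels must be >= 1")
        if self.exemplars_per_condition < 2:
            raise ValidationError("need >= 2 exemplars per condition")
        if self.trials_per_subject < 1:
            raise ValidationError("trials_per_subject must be >= 1")

    # -- (de)serialization ------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        # tuples do not round-trip through YAML; store cell means as lists
        d["psc_cell_means"] = {
            a: {r: {h: list(v) for h, v in cell.items()}
                for r, cell in ranges.items()}
            for a, ranges in d["psc_cell_means"].items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        known = set(cls.__dataclass_fields__)
        for key in d:
            if key not in known:
                raise SchemaError(key)
        d = dict(d)
        if "psc_cell_means" in d:
            d["psc_cell_means"] = {
                a: {r: {h: tuple(v) for h, v in cell.items()}
                    for r, cell in ranges.items()}
                for a, ranges in d["psc_cell_means"].items()
            }
        return cls(**d)


@dataclass
class SyntheticDataset:
    """One complete simulated study: patterns, PSC records, trials, and the
    ground truth (config plus per-subject voxel preferences) that produced
    them."""

    pattern_sets: list[PatternSet]
    psc_records: pd.DataFrame
    trial_records: pd.DataFrame
    ground_truth: dict


def _design_center(arrangement: str, numerosity: int) -> float:
    """Centered numerosity relative to the balanced design cell mean."""
    rng_ = number_range(numerosity)
    lo, hi = NUMEROSITY_RANGE[arrangement]
    if rng_ == "subitizing":
        cell = [n for n in range(lo, hi + 1) if n <= 4]
    else:
        cell = [n for n in range(lo, hi + 1) if n >= 5]
    return numerosity - float(np.mean(cell))


def _subject_ids(n: int) -> list[str]:
    return [f"s{i:02d}" for i in range(1, n + 1)]


def sample_voxel_tuning(n_voxels: int, seed) -> np.ndarray:
    """Preferred numerosities of simulated voxels, log-uniform on [1, 10].

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if n_voxels < 1:
        raise ValidationError("n_voxels must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return np.exp(rng.uniform(0.0, np.log(10.0), size=int(n_voxels)))


def generate_patterns(config: GeneratorConfig, seed: int | None = None,
                      return_tuning: bool = False):
    """Voxel-pattern exemplars for every subject and valid condition.

    The noiseless response of voxel ``v`` (preference ``p_v``) to
    numerosity ``n`` under arrangement ``arr`` is the Gaussian tuning
    density itself, ``gain * f(n; p_v, w_arr)`` with standard deviation
    ``w_arr * p_v`` — so narrower tuning yields taller, more selective
    responses, which is what makes narrow-width arrangements more
    decodable.  Exemplars add independent Gaussian noise; voxel
    preferences are fixed within a subject and resampled across subjects.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    conditions = valid_conditions()
    sets: list[PatternSet] = []
    tuning: dict[str, np.ndarray] = {}
    for sid in _subject_ids(config.n_subjects):
        prefs = sample_voxel_tuning(config.n_voxels, rng)
        tuning[sid] = prefs
        for cond in conditions:
            w = config.widths[cond.arrangement]
            sd = w * prefs
            mean = config.pattern_gain / (np.sqrt(2.0 * np.pi) * sd) * np.exp(
                -((cond.numerosity - prefs) ** 2) / (2.0 * sd**2)
            )
            noise = rng.normal(
                0.0, config.pattern_noise_sd,
                size=(config.exemplars_per_condition, config.n_voxels),
            )
            sets.append(PatternSet(sid, cond, mean[None, :] + noise))
    if return_tuning:
        return sets, tuning
    return sets


def generate_psc(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Percent-signal-change records: one row per subject x hemisphere x
    condition.

    ``psc = cell_mean + slope * centered_n + subject_intercept + noise``;
    the residual SD is chosen so the total between-subject SD matches the
    configured cell SD (``resid_sd^2 = cell_sd^2 - subject_sd^2``, floored at zero).
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    rows = []
    for sid in _subject_ids(config.n_subjects):
        intercept = rng.normal(0.0, config.psc_subject_sd)
        for cond in valid_conditions():
            rng_name = cond.range
            centered = _design_center(cond.arrangement, cond.numerosity)
            slope = config.psc_slopes[cond.arrangement][rng_name]
            for hemi in ("left", "right"):
                mean, sd = config.psc_cell_means[cond.arrangement][rng_name][hemi]
                resid_sd = np.sqrt(max(sd**2 - config.psc_subject_sd**2, 0.0))
                noise = rng.normal(0.0, resid_sd) if resid_sd > 0 else 0.0
                rows.append(
                    {
                        "subject_id": sid,
                        "hemisphere": hemi,
                        "arrangement": cond.arrangement,
                        "numerosity": cond.numerosity,
                        "psc": mean + slope * centered + intercept + noise,
                    }
                )
    return pd.DataFrame(rows)


def generate_behavior(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Trial-level behavioral records (RT in ms, correctness, run).

    Each subject completes ``trials_per_subject`` trials balanced over the
    19 conditions; the remainder after integer division is assigned to a
    seed-deterministic subset of conditions.  Correctness is Bernoulli with
    error probability ``invlogit(cell_log_odds + subject_er_intercept)``;
    RTs are log-normal around the cell log-mean plus a numerosity slope and
    a subject intercept.  A configurable fraction of trials is replaced by
    fast guesses uniform on [50, 200) ms.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    conditions = valid_conditions()
    k = len(conditions)
    base, rem = divmod(config.trials_per_subject, k)
    rows = []
    for sid in _subject_ids(config.n_subjects):
        rt_intercept = rng.normal(0.0, config.rt_subject_sd)
        er_intercept = rng.normal(0.0, config.er_subject_sd)
        counts = np.full(k, base)
        if rem:
            counts[rng.choice(k, size=rem, replace=False)] += 1
        conds: list[ConditionLabel] = []
        for cond, c in zip(conditions, counts):
            conds.extend([cond] * int(c))
        order = rng.permutation(len(conds))
        half = len(conds) // 2
        for trial_pos, ci in enumerate(order):
            cond = conds[ci]
            rng_name = cond.range
            centered = _design_center(cond.arrangement, cond.numerosity)
            log_odds = config.er_log_odds[cond.arrangement][rng_name] + er_intercept
            p_err = 1.0 / (1.0 + np.exp(-log_odds))
            correct = bool(rng.random() >= p_err)
            mu = (
                config.rt_log_means[cond.arrangement][rng_name]
                + config.rt_slopes[cond.arrangement][rng_name] * centered
                + rt_intercept
            )
            rt = float(np.exp(rng.normal(mu, config.rt_noise_sd)))
            if config.fast_guess_rate and rng.random() < config.fast_guess_rate:
                rt = float(rng.uniform(50.0, 200.0))
            rows.append(
                {
                    "subject_id": sid,
                    "arrangement": cond.arrangement,
                    "numerosity": cond.numerosity,
                    "rt_ms": rt,
                    "correct": correct,
                    "run": 1 if trial_pos < half else 2,
                }
            )
    return pd.DataFrame(rows)


def simulate_dataset(config: GeneratorConfig | None = None,
                     seed: int | None = None) -> SyntheticDataset:
    """Generate all three modalities and bundle them with their ground truth."""
    config = config or GeneratorConfig()
    seed = config.seed if seed is None else seed
    patterns, tuning = generate_patterns(config, seed=seed, return_tuning=True)
    psc = generate_psc(config, seed=seed)
    trials = generate_behavior(config, seed=seed)
    truth = {
        "config": config.to_dict(),
        "seed": int(seed),
        "voxel_tuning": {sid: prefs.tolist() for sid, prefs in tuning.items()},
    }
    return SyntheticDataset(patterns, psc, trials, truth)
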