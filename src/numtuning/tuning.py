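"""Gaussian numerosity tuning: density, overlap, and width estimation.

The approximate number system represents a numerosity ``n`` by a bell-shaped
tuning curve on a linear number line whose spread grows proportionally with
``n`` (scalar variability).  The tuning density used throughout this package
is the normal density with mean ``n`` and standard deviation ``w * n``:

    f(x; n, w) = 1 / (sqrt(2 pi) w n) * exp(-(x - n)^2 / (2 (w n)^2))

``w`` is the dimensionless tuning width: small ``w`` means precise, well
separated representations; large ``w`` means heavily overlapping ones.

Width estimation follows the statsmodels model/results idiom:
:class:`GaussianTuningModel` holds the observed similarity curves, its
:meth:`~GaussianTuningModel.fit` runs a Levenberg-Marquardt nonlinear least
squares in ``log w`` (and optionally ``log scale``) and returns a
:class:`TuningFit`.  :func:`fit_tuning_width` is the functional shortcut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import DomainError, InsufficientDataError

__all__ = [
    "tuning_density",
    "curve_overlap",
    "NumerosityCurve",
    "TuningParams",
    "GaussianTuningModel",
    "TuningFit",
    "fit_tuning_width",
]


@dataclass(frozen=True)
class TuningParams:
    """Parameters of the tuning density: width fraction ``w`` and an
    optional multiplicative ``scale`` (1.0 reproduces the bare density)."""

    w: float
    scale: float = 1.0

    def __post_init__(self):
        if not (self.w > 0):
            raise DomainError(f"tuning width w must be > 0, got {self.w}")
        if not (self.scale > 0):
            raise DomainError(f"scale must be > 0, got {self.scale}")


def tuning_density(x, n, w):
    """Gaussian tuning density of numerosity ``n`` evaluated at probe ``x``.

    Mean ``n``, standard deviation ``w * n`` — the scalar-variability
    signature that makes curves for larger numerosities proportionally
    wider and flatter.  Broadcasts over array inputs.

    Parameters
    ----------
    x : array_like
        Probe numerosity (any real).
    n : array_like
        Reference numerosity, strictly positive.
    w : array_like
        Dimensionless width fraction, strictly positive.

    Returns
    -------
    ndarray or float
        Strictly positive density values; the maximum over ``x`` sits at
        ``x == n`` with height ``1 / (sqrt(2 pi) w n)``.
    """
    n = np.asarray(n, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(n <= 0):
        raise DomainError("reference numerosity n must be > 0")
    if np.any(w <= 0):
        raise DomainError("tuning width w must be > 0")
    return stats.norm.pdf(np.asarray(x, dtype=float), loc=n, scale=w * n)


def curve_overlap(n1: float, n2: float, w: float, num: int = 20001) -> float:
    """Overlap coefficient between the tuning curves of two numerosities.

    Computes ``integral of min(f(x; n1, w), f(x; n2, w)) dx`` on a grid
    covering both curves out to 12 standard deviations.  The result lies in
    [0, 1], equals 1 for identical curves, and is symmetric in (n1, n2).
    Because widths scale with n, the overlap of consecutive numerosities
    grows with n — the tuning-model explanation of the size effect.
    """
    if n1 <= 0 or n2 <= 0:
        raise DomainError("numerosities must be > 0")
    if w <= 0:
        raise DomainError("tuning width w must be > 0")
    if n1 == n2:
        return 1.0
    sd_max = w * max(n1, n2)
    lo = min(n1, n2) - 12.0 * sd_max
    hi = max(n1, n2) + 12.0 * sd_max
    x = np.linspace(lo, hi, num)
    f1 = tuning_density(x, n1, w)
    f2 = tuning_density(x, n2, w)
    return float(np.trapezoid(np.minimum(f1, f2), x))


@dataclass
class NumerosityCurve:
    """A similarity curve: classification errors of one reference
    numerosity against a set of probe numerosities.

    ``values[i]`` is the similarity (classification error, in [0, 1]) between
    the reference condition and the probe ``probes[i]``.
    """

    reference_n: int
    probes: list[int]
    values: list[float]

    def __post_init__(self):
        probes = list(self.probes)
        values = [float(v) for v in self.values]
        if len(values) != len(probes):
            raise DomainError("probes and values must have equal length")
        if any(b <= a for a, b in zip(probes, probes[1:])):
            raise DomainError("probes must be strictly increasing")
        if any(not 0.0 <= v <= 1.0 for v in values):
            raise DomainError("curve values must lie in [0, 1]")
        self.probes = probes
        self.values = values


@dataclass
class TuningFit:
    """Results of a tuning-width fit (returned by ``GaussianTuningModel.fit``)."""

    w_hat: float
    scale_hat: float
    sse: float
    converged: bool
    n_points: int
    start_w: float
    n_iter: int = 0
    arrangement: str | None = None

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        rows = [
            ("arrangement", self.arrangement or "-"),
            ("tuning width w", f"{self.w_hat:.4f}"),
            ("scale", f"{self.scale_hat:.4f}"),
            ("SSE", f"{self.sse:.6g}"),
            ("n points", str(self.n_points)),
            ("start w", f"{self.start_w:.3f}"),
            ("converged", str(self.converged)),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["Gaussian tuning width fit", "=" * 25]
        lines += [f"{k.ljust(width)}  {v}" for k, v in rows]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "arrangement": self.arrangement,
                    "w_hat": self.w_hat,
                    "scale_hat": self.scale_hat,
                    "sse": self.sse,
                    "converged": self.converged,
                    "n_points": self.n_points,
                }
            ]
        )


class GaussianTuningModel:
    """Nonlinear least-squares estimator of the tuning width ``w``.

    The model predicts each observed similarity value by
    ``scale * f(probe; reference_n, w)`` and minimizes the sum of squared
    residuals jointly over all curves — one ``w`` (and one ``scale``) per
    model, matching the convention of one width per arrangement.

    Self-similarity points (probe == reference) are excluded by default: a
    two-class decoder cannot be run on a condition against itself, so the
    diagonal of a classification-error matrix is undefined.  Passing
    ``include_self=True`` appends synthetic diagonal points at a fixed
    chance error instead.

    Parameters
    ----------
    curves : sequence of NumerosityCurve
    include_self : bool
        Append (n, n) points at ``chance_value``.
    chance_value : float
        Error rate assigned to self pairs when included.
    """

    #: SSE-change convergence tolerance and iteration cap of the damped
    #: Gauss-Newton (Levenberg-Marquardt) iteration.
    ftol = 1e-8
    max_iter = 500

    def __init__(self, curves, include_self: bool = False, chance_value: float = 0.5):
        ns, xs, ys = [], [], []
        for c in curves:
            for p, v in zip(c.probes, c.values):
                if p == c.reference_n and not include_self:
                    continue
                ns.append(float(c.reference_n))
                xs.append(float(p))
                ys.append(float(v))
            if include_self and c.reference_n not in c.probes:
                ns.append(float(c.reference_n))
                xs.append(float(c.reference_n))
                ys.append(float(chance_value))
        self.n = np.asarray(ns)
        self.x = np.asarray(xs)
        self.y = np.asarray(ys)
        if len(self.y) < 2:
            raise InsufficientDataError(
                "need at least 2 (reference, probe) pairs to fit a tuning width"
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "GaussianTuningModel":
        """Build from a tidy curve table with columns
        ``reference_n``, ``probe_n``, ``error_rate`` (``arrangement`` ignored)."""
        curves = []
        for ref, grp in df.groupby("reference_n"):
            grp = grp.sort_values("probe_n")
            curves.append(
                NumerosityCurve(
                    int(ref),
                    grp["probe_n"].astype(int).tolist(),
                    grp["error_rate"].astype(float).tolist(),
                )
            )
        return cls(curves, **kwargs)

    def predict(self, w: float, scale: float = 1.0) -> np.ndarray:
        return scale * tuning_density(self.x, self.n, w)

    def sse(self, w: float, scale: float = 1.0) -> float:
        r = self.y - self.predict(w, scale)
        return float(r @ r)

    def fit(self, start_w: float = 0.4, fit_scale: bool = True) -> TuningFit:
        """Minimize the SSE over ``w`` (and ``scale``) from ``start_w``.

        Positivity is enforced by optimizing ``log w`` (and ``log scale``);
        hitting the iteration cap yields ``converged=False`` rather than an
        exception.
        """
        if not start_w > 0:
            raise DomainError("start_w must be > 0")

        if not fit_scale and np.ptp(self.y) == 0.0:
            # a flat curve carries no shape information about w
            return TuningFit(
                w_hat=start_w, scale_hat=1.0, sse=self.sse(start_w), converged=False,
                n_points=len(self.y), start_w=start_w,
            )

        if fit_scale:
            def resid(theta):
                return self.y - np.exp(theta[1]) * tuning_density(
                    self.x, self.n, np.exp(theta[0])
                )
            theta0 = [np.log(start_w), 0.0]
        else:
            def resid(theta):
                return self.y - tuning_density(self.x, self.n, np.exp(theta[0]))
            theta0 = [np.log(start_w)]

        res = optimize.least_squares(
            resid, theta0, method="lm",
            ftol=self.ftol, xtol=1e-12, gtol=1e-12,
            max_nfev=self.max_iter,
        )
        w_hat = float(np.exp(res.x[0]))
        scale_hat = float(np.exp(res.x[1])) if fit_scale else 1.0
        return TuningFit(
            w_hat=w_hat,
            scale_hat=scale_hat,
            sse=float(res.cost * 2.0),
            converged=bool(res.status > 0),
            n_points=len(self.y),
            start_w=start_w,
            n_iter=int(res.nfev),
        )


def fit_tuning_width(
    curves,
    start_w: float = 0.4,
    fit_scale: bool = True,
    include_self: bool = False,
    chance_value: float = 0.5,
) -> TuningFit:
    """Estimate the tuning width from similarity curves (see
    :class:`GaussianTuningModel`)."""
    model = GaussianTuningModel(
        curves, include_self=include_self, chance_value=chance_value
    )
    return model.fit(start_w=start_w, fit_scale=fit_scale)
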