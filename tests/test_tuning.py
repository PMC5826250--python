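"""Tuning density, overlap statistic, and width estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from numtuning import (
    DomainError,
    GaussianTuningModel,
    InsufficientDataError,
    NumerosityCurve,
    TuningParams,
    curve_overlap,
    fit_tuning_width,
    tuning_density,
)


def make_exact_curves(w, scale=1.0, ns=range(2, 9), probes=range(2, 9)):
    """Curves lying exactly on scale * f(x; n, w)."""
    curves = []
    for n in ns:
        ps = [p for p in probes if p != n]
        vals = [float(scale * tuning_density(p, n, w)) for p in ps]
        curves.append(NumerosityCurve(n, ps, vals))
    return curves


def grid_search_w(model, grid):
    """Independent dense-grid SSE minimizer with the scale profiled out.

    For fixed w the optimal scale is linear-least-squares:
    scale = <y, f> / <f, f>.
    """
    best_w, best_sse, best_scale = None, np.inf, None
    for w in grid:
        f = tuning_density(model.x, model.n, w)
        scale = float(model.y @ f) / float(f @ f)
        sse = float(((model.y - scale * f) ** 2).sum())
        if sse < best_sse:
            best_w, best_sse, best_scale = w, sse, scale
    return best_w, best_scale, best_sse


class TestTuningDensity:
    def test_peak_values_match_closed_form(self):
        # peak height is 1 / (sqrt(2 pi) w n)
        assert tuning_density(5, 5, 0.276) == pytest.approx(0.2891, abs=1e-4)
        assert tuning_density(3, 3, 0.094) == pytest.approx(1.4147, abs=1e-4)

    @given(
        n=st.integers(2, 8),
        w=st.floats(0.05, 1.0),
        d=st.floats(0.01, 5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetry_about_reference(self, n, w, d):
        assert tuning_density(n + d, n, w) == pytest.approx(
            tuning_density(n - d, n, w), rel=1e-12
        )

    @pytest.mark.parametrize("n", range(2, 9))
    @pytest.mark.parametrize("w", [0.094, 0.241, 0.276, 0.8])
    def test_normalization(self, n, w):
        # numerical integral over +-10 sd equals 1 to 1e-6
        x = np.linspace(n - 10 * w * n, n + 10 * w * n, 20001)
        integral = np.trapezoid(tuning_density(x, n, w), x)
        assert integral == pytest.approx(1.0, abs=1e-6)

    def test_peak_height_decreases_with_n(self):
        # scalar variability: larger sets have flatter curves (size effect)
        peaks = [tuning_density(n, n, 0.2) for n in range(2, 9)]
        assert all(a > b for a, b in zip(peaks, peaks[1:]))

    @pytest.mark.parametrize("bad", [{"n": 0}, {"n": -1}, {"w": 0}, {"w": -0.5}])
    def test_domain_errors(self, bad):
        kwargs = {"x": 3.0, "n": 3.0, "w": 0.2} | bad
        with pytest.raises(DomainError):
            tuning_density(**kwargs)

    def test_params_invariants(self):
        with pytest.raises(DomainError):
            TuningParams(w=-0.1)
        with pytest.raises(DomainError):
            TuningParams(w=0.2, scale=0.0)


class TestCurveOverlap:
    def test_identical_curves_overlap_fully(self):
        assert curve_overlap(4, 4, 0.3) == pytest.approx(1.0)

    def test_symmetric(self):
        assert curve_overlap(2, 5, 0.2) == pytest.approx(
            curve_overlap(5, 2, 0.2), abs=1e-12
        )

    def test_overlap_grows_with_numerosity(self):
        # widths scale with n, so equal spacing overlaps more at larger n
        assert curve_overlap(5, 6, 0.2) > curve_overlap(2, 3, 0.2)

    def test_narrow_tuning_overlaps_less(self):
        assert curve_overlap(2, 3, 0.094) < curve_overlap(2, 3, 0.276)

    @pytest.mark.parametrize("w", [0.094, 0.276])
    def test_consecutive_overlap_nondecreasing(self, w):
        vals = [curve_overlap(n, n + 1, w) for n in range(2, 8)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            curve_overlap(0, 3, 0.2)
        with pytest.raises(DomainError):
            curve_overlap(2, 3, -0.1)


class TestNumerosityCurve:
    def test_invariants_enforced(self):
        with pytest.raises(DomainError):
            NumerosityCurve(3, [2, 2, 5], [0.1, 0.2, 0.3])  # not increasing
        with pytest.raises(DomainError):
            NumerosityCurve(3, [2, 4], [0.1])  # length mismatch
        with pytest.raises(DomainError):
            NumerosityCurve(3, [2, 4], [0.1, 1.3])  # out of [0, 1]


class TestFitTuningWidth:
    def test_noise_free_self_consistency(self):
        fit = fit_tuning_width(make_exact_curves(w=0.25), fit_scale=True)
        assert fit.converged
        assert fit.w_hat == pytest.approx(0.25, abs=1e-6)
        assert fit.scale_hat == pytest.approx(1.0, abs=1e-6)
        assert fit.sse == pytest.approx(0.0, abs=1e-12)

    def test_matches_grid_search_oracle_on_noisy_data(self):
        # 20 seeded noisy datasets; LM fit agrees with a dense grid search
        grid = np.arange(0.02, 1.0, 1e-4)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            curves = make_exact_curves(w=0.15, scale=0.8)
            noisy = [
                NumerosityCurve(
                    c.reference_n,
                    c.probes,
                    list(np.clip(np.array(c.values) + rng.normal(0, 0.01, len(c.values)), 0, 1)),
                )
                for c in curves
            ]
            model = GaussianTuningModel(noisy)
            fit = model.fit()
            w_grid, _, _ = grid_search_w(model, grid)
            assert fit.w_hat == pytest.approx(w_grid, abs=1e-3)

    def test_parameter_recovery_mean_within_5_percent(self):
        # 200 replicates at w = 0.10, noise sd 0.005
        w_hats = []
        rng = np.random.default_rng(42)
        for _ in range(200):
            curves = make_exact_curves(w=0.10, scale=1.0)
            noisy = [
                NumerosityCurve(
                    c.reference_n,
                    c.probes,
                    list(np.clip(np.array(c.values) + rng.normal(0, 0.005, len(c.values)), 0, 1)),
                )
                for c in curves
            ]
            w_hats.append(fit_tuning_width(noisy).w_hat)
        assert np.mean(w_hats) == pytest.approx(0.10, rel=0.05)

    def test_fit_invariant_to_curve_and_probe_order(self):
        curves = make_exact_curves(w=0.3, scale=0.6)
        rng = np.random.default_rng(0)
        noisy = [
            NumerosityCurve(
                c.reference_n,
                c.probes,
                list(np.clip(np.array(c.values) + rng.normal(0, 0.02, len(c.values)), 0, 1)),
            )
            for c in curves
        ]
        fit_fwd = fit_tuning_width(noisy)
        fit_rev = fit_tuning_width(list(reversed(noisy)))
        assert fit_fwd.w_hat == pytest.approx(fit_rev.w_hat, abs=1e-9)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            fit_tuning_width([NumerosityCurve(3, [4], [0.3])])

    def test_flat_curve_without_scale_flagged_not_raised(self):
        curves = [NumerosityCurve(3, [2, 4, 5], [0.2, 0.2, 0.2])]
        fit = fit_tuning_width(curves, fit_scale=False)
        assert not fit.converged

    def test_self_pairs_excluded_by_default(self):
        curves = [NumerosityCurve(3, [2, 3, 4], [0.1, 0.5, 0.1])]
        model = GaussianTuningModel(curves)
        assert model.n.shape == (2,)
        model_with = GaussianTuningModel(curves, include_self=True)
        assert model_with.n.shape == (3,)

    def test_bad_start_raises(self):
        with pytest.raises(DomainError):
            fit_tuning_width(make_exact_curves(w=0.2), start_w=0.0)

    def test_summary_mentions_width(self):
        fit = fit_tuning_width(make_exact_curves(w=0.25))
        assert "tuning width" in fit.summary()
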