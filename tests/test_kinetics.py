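"""Kinetic-trace estimators: spreading, melting, coverage, fusion, recoil."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from activewet.kinetics import (FusionPair, KineticTrace, apical_response,
                                fit_fusion, fit_fusion_scaling,
                                fit_melting_rate, fit_recoil,
                                fit_spreading_rate, two_segment_regression)


def trace(t, y, **kw):
    return KineticTrace(t=np.asarray(t, float), y=np.asarray(y, float), **kw)


class TestSpreadingRate:
    def test_exact_line(self):
        t = np.linspace(0.0, 20.0, 30)
        fit = fit_spreading_rate(trace(t, 1000.0 + 500.0 * t), A0=1000.0)
        assert fit.converged
        assert fit.params["dA_dt"] == pytest.approx(500.0, rel=1e-12)

    def test_gate_excludes_early_points_without_changing_slope(self):
        t = np.linspace(0.0, 10.0, 21)
        y = 1000.0 + 100.0 * t  # first 3 points below 1.2 * 1000
        fit = fit_spreading_rate(trace(t, y), A0=1000.0)
        assert fit.n_points == int((y > 1200.0).sum())
        assert fit.params["dA_dt"] == pytest.approx(100.0, rel=1e-12)

    def test_t_max_cut(self):
        t = np.linspace(0.0, 48.0, 97)
        y = np.where(t <= 24, 2000.0 + 500.0 * t, 14000.0)  # plateau after 24 h
        fit = fit_spreading_rate(trace(t, y), A0=1000.0, t_max=24.0)
        assert fit.params["dA_dt"] == pytest.approx(500.0, rel=1e-9)

    def test_noisy_slope_within_uncertainty(self, rng):
        t = np.linspace(0.0, 24.0, 49)
        y0 = 5000.0 + 450.0 * t
        y = y0 + rng.normal(0.0, 0.02 * y0.mean(), t.size)
        fit = fit_spreading_rate(trace(t, y), A0=1000.0)
        assert abs(fit.params["dA_dt"] - 450.0) <= 3 * fit.stderr["dA_dt"]

    def test_too_few_gated_points_flagged(self):
        t = np.linspace(0.0, 5.0, 10)
        fit = fit_spreading_rate(trace(t, np.full_like(t, 1000.0)), A0=1000.0)
        assert not fit.converged


class TestMeltingRate:
    def test_exact_line(self):
        t = np.linspace(0.0, 20.0, 21)
        fit = fit_melting_rate(trace(t, 0.8 - 0.02 * t))
        assert fit.params["rate"] == pytest.approx(-0.02, rel=1e-12)

    def test_constant_trace_zero_slope(self):
        t = np.linspace(0.0, 10.0, 11)
        fit = fit_melting_rate(trace(t, np.full_like(t, 0.8)))
        assert fit.params["rate"] == pytest.approx(0.0, abs=1e-15)

    def test_noisy_within_uncertainty(self, rng):
        t = np.linspace(0.0, 24.0, 25)
        y = 0.9 - 0.015 * t + rng.normal(0.0, 0.01, t.size)
        fit = fit_melting_rate(trace(t, y))
        assert abs(fit.params["rate"] + 0.015) <= 3 * fit.stderr["rate"]


def naive_two_segment(t, y, min_per_segment=3):
    """Independent exhaustive-search oracle with the same tie rule."""
    scale = float(np.sum((y - y.mean()) ** 2)) + 1e-300
    tol = 1e-10 * scale
    best = None
    for k in range(min_per_segment - 1, t.size - min_per_segment):
        X = np.column_stack([np.ones_like(t), t, np.maximum(t - t[k], 0.0)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(np.sum((X @ coef - y) ** 2))
        if best is None or sse < best[0] - tol:
            best = (sse, coef[1], coef[1] + coef[2], t[k])
    return best


class TestTwoSegment:
    def test_exact_piecewise_line(self):
        t = np.linspace(0.0, 6.0, 13)
        y = np.where(t <= 2.0, 1.0, 1.0 + 5.0 * (t - 2.0))
        fit = two_segment_regression(trace(t, y))
        s1, s2, bp = fit
        assert s1 == pytest.approx(0.0, abs=1e-10)
        assert s2 == pytest.approx(5.0, rel=1e-10)
        assert bp == pytest.approx(2.0)

    def test_single_line_earliest_breakpoint(self):
        t = np.linspace(0.0, 10.0, 12)
        fit = two_segment_regression(trace(t, 2.0 + 3.0 * t))
        assert fit.breakpoint_index == 2  # earliest admissible interior index
        assert fit.slope1 == pytest.approx(3.0, rel=1e-9)
        assert fit.slope2 == pytest.approx(3.0, rel=1e-9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 25))
        t = np.sort(rng.uniform(0.0, 10.0, n))
        t += np.arange(n) * 1e-6  # strict monotonicity
        bp = rng.uniform(t[3], t[-4])
        y = (rng.normal(0, 0.5) * t + np.maximum(t - bp, 0) * rng.normal(0, 3)
             + rng.normal(0, 0.2, n))
        fit = two_segment_regression(trace(t, y))
        sse, s1, s2, tb = naive_two_segment(t, y)
        assert fit.breakpoint == tb
        assert fit.slope1 == pytest.approx(s1, rel=1e-9, abs=1e-12)
        assert fit.slope2 == pytest.approx(s2, rel=1e-9, abs=1e-12)

    def test_too_few_points(self):
        t = np.linspace(0, 1, 6)
        with pytest.raises(ValueError):
            two_segment_regression(trace(t, t))


class TestFusion:
    def test_noiseless_round_trip_on_imaging_times(self):
        t = np.array([1.0, 8.0, 24.0, 48.0, 72.0])
        y = 1.0 * (1.0 - np.exp(-0.2 * t))
        fit = fit_fusion(trace(t, y))
        assert fit.params["gamma"] == pytest.approx(0.2, abs=1e-6)
        assert fit.params["amplitude"] == pytest.approx(1.0, abs=1e-6)
        assert fit.extra["classification"] == "complete"

    def test_arrested_coalescence_classified(self):
        t = np.array([1.0, 8.0, 24.0, 48.0, 72.0])
        y = 0.6 * (1.0 - np.exp(-0.15 * t))
        fit = fit_fusion(trace(t, y))
        assert fit.params["amplitude"] == pytest.approx(0.6, abs=1e-6)
        assert fit.extra["classification"] == "arrested"

    def test_zero_trace_flagged(self):
        t = np.array([1.0, 8.0, 24.0, 48.0, 72.0])
        fit = fit_fusion(trace(t, np.zeros_like(t)))
        assert not fit.converged

    def test_noisy_recovery(self, rng):
        t = np.array([1.0, 8.0, 24.0, 48.0, 72.0])
        y = 0.8 * (1.0 - np.exp(-0.1 * t)) + rng.normal(0.0, 0.03, t.size)
        fit = fit_fusion(trace(t, y))
        assert abs(fit.params["gamma"] - 0.1) <= 3 * fit.stderr["gamma"]
        assert abs(fit.params["amplitude"] - 0.8) <= 3 * fit.stderr["amplitude"]

    def test_amplitude_bound_respected(self, rng):
        t = np.array([1.0, 8.0, 24.0, 48.0, 72.0])
        y = 1.3 * (1.0 - np.exp(-0.2 * t))  # above the physical bound
        fit = fit_fusion(trace(t, y))
        assert fit.params["amplitude"] <= 1.2 + 1e-9


class TestFusionScaling:
    def make_pairs(self, sigma_over_eta=0.1, radii=(50.0, 100.0, 200.0), gammas=None):
        pairs = []
        for i, r0 in enumerate(radii):
            g = sigma_over_eta / r0 if gammas is None else gammas[i]
            pairs.append(FusionPair(R0=r0, gamma=g, amplitude=1.0))
        return pairs

    def test_exact_construction(self):
        fit = fit_fusion_scaling(self.make_pairs(0.1), units="um/s")
        assert fit.params["sigma_over_eta"] == pytest.approx(0.1, rel=1e-12)
        assert fit.extra["units"] == "um/s"

    def test_doubled_rates_double_ratio(self):
        base = self.make_pairs(0.1)
        doubled = [FusionPair(R0=p.R0, gamma=2 * p.gamma, amplitude=1.0)
                   for p in base]
        f1 = fit_fusion_scaling(base)
        f2 = fit_fusion_scaling(doubled)
        assert f2.params["sigma_over_eta"] == pytest.approx(
            2 * f1.params["sigma_over_eta"], rel=1e-12)

    def test_noisy_within_uncertainty(self, rng):
        radii = np.repeat([50.0, 100.0, 200.0], 5)
        gammas = 0.1 / radii * (1 + 0.1 * rng.normal(size=radii.size))
        pairs = [FusionPair(R0=r, gamma=g, amplitude=1.0)
                 for r, g in zip(radii, gammas)]
        fit = fit_fusion_scaling(pairs)
        assert abs(fit.params["sigma_over_eta"] - 0.1) <= 3 * fit.stderr["sigma_over_eta"]

    def test_free_intercept_variant(self):
        fit = fit_fusion_scaling(self.make_pairs(0.2), through_origin=False)
        assert fit.params["sigma_over_eta"] == pytest.approx(0.2, rel=1e-9)

    def test_degenerate_radii_rejected(self):
        pairs = [FusionPair(R0=100.0, gamma=0.001, amplitude=1.0)] * 3
        with pytest.raises(ValueError):
            fit_fusion_scaling(pairs)


class TestRecoil:
    def test_noiseless_round_trip(self):
        t = np.linspace(0.0, 20.0, 21)
        y = (1.2 / 0.5) * (1.0 - np.exp(-0.5 * t))
        fit = fit_recoil(trace(t, y, t_units="s", y_units="um"))
        assert fit.params["initial_recoil"] == pytest.approx(1.2, rel=1e-6)
        assert fit.params["k"] == pytest.approx(0.5, rel=1e-6)

    def test_flat_trace_zero_recoil(self):
        t = np.linspace(0.0, 20.0, 21)
        fit = fit_recoil(trace(t, np.zeros_like(t)))
        assert fit.converged
        assert fit.params["initial_recoil"] == 0.0

    def test_noisy_recovery(self, rng):
        t = np.linspace(0.0, 20.0, 41)
        y0 = (1.2 / 0.5) * (1.0 - np.exp(-0.5 * t))
        y = y0 + rng.normal(0.0, 0.05 * y0.max(), t.size)
        fit = fit_recoil(trace(t, y))
        assert abs(fit.params["initial_recoil"] - 1.2) <= 3 * fit.stderr["initial_recoil"]
        assert abs(fit.params["k"] - 0.5) <= 3 * fit.stderr["k"]


class TestApicalResponse:
    def test_constant_trace(self):
        t = np.array([0.0, 1.5, 3.0, 4.5])
        assert apical_response(trace(t, np.ones_like(t))) == 0.0

    def test_linear_interpolation_exact(self):
        t = np.array([0.0, 1.5, 3.0])
        y = 1.0 + 0.05 * t / 3.0
        assert apical_response(trace(t, y)) == pytest.approx(0.05, rel=1e-12)

    def test_smooth_trace_interpolation_error_bound(self):
        t = np.linspace(0.0, 4.0, 9)
        y = 1.0 + 0.1 * np.sin(t / 2.0)
        analytic = 0.1 * np.sin(1.5)
        # linear interpolation error <= h^2/8 * max|y''|
        bound = (0.5**2 / 8) * 0.1 * 0.25
        assert abs(apical_response(trace(t, y)) - analytic) <= bound + 1e-15

    def test_short_trace_rejected(self):
        t = np.array([0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            apical_response(trace(t, np.ones_like(t)), t_probe=3.0)


class TestUnitEquivariance:
    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_fusion_rate_rescales_with_time(self, seed):
        """Rescaling t by c rescales Gamma by 1/c and leaves amplitude fixed."""
        rng = np.random.default_rng(seed)
        t = np.array([1.0, 8.0, 24.0, 48.0, 72.0])
        a, g = rng.uniform(0.5, 1.0), rng.uniform(0.05, 0.5)
        y = a * (1.0 - np.exp(-g * t)) + rng.normal(0, 0.01, t.size)
        f1 = fit_fusion(trace(t, y))
        f2 = fit_fusion(trace(t * 60.0, y))  # hours -> minutes
        assert f2.params["gamma"] == pytest.approx(f1.params["gamma"] / 60.0,
                                                   rel=1e-5)
        assert f2.params["amplitude"] == pytest.approx(f1.params["amplitude"],
                                                       rel=1e-6)
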