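"""Vector-field summaries: centroids, radial profiles, order parameters, correlation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from activewet.fields import (RadialProfile, VectorField, centroid,
                              correlation_length, order_parameters,
                              radial_profile, rolling_smooth, smooth_profiles)
from activewet.synthetic import gen_correlated_field

from conftest import profile_from_arrays, uniform_field


def make_field(u, v, mask=None, spacing=10.0):
    u = np.asarray(u, dtype=float)
    ny, nx = u.shape
    return VectorField(
        grid_x=np.arange(nx) * spacing, grid_y=np.arange(ny) * spacing,
        u=u, v=np.asarray(v, dtype=float),
        mask=np.ones_like(u, dtype=bool) if mask is None else mask,
    )


class TestCentroid:
    def test_centered_disk(self):
        yy, xx = np.indices((100, 100))
        mask = np.hypot(xx - 49.5, yy - 49.5) <= 20
        assert centroid(mask, 1.0) == pytest.approx((49.5, 49.5))

    def test_single_pixel(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[10, 30] = True
        assert centroid(mask, 2.0) == (60.0, 20.0)  # (x, y) = (col, row) * ps

    def test_half_disk_matches_brute_force(self):
        yy, xx = np.indices((80, 80))
        mask = (np.hypot(xx - 40, yy - 40) <= 25) & (xx >= 40)
        cx, cy = centroid(mask, 1.5)
        iy, ix = np.nonzero(mask)
        assert cx == pytest.approx(ix.mean() * 1.5)
        assert cy == pytest.approx(iy.mean() * 1.5)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            centroid(np.zeros((5, 5), dtype=bool))


class TestRadialProfile:
    def center_and_geometry(self, shape=(21, 21), spacing=10.0):
        cx = (shape[1] - 1) / 2 * spacing
        cy = (shape[0] - 1) / 2 * spacing
        X, Y = np.meshgrid(np.arange(shape[1]) * spacing,
                           np.arange(shape[0]) * spacing)
        return (cx, cy), X - cx, Y - cy

    def test_pure_radial_field_constant_bins(self):
        (cx, cy), dx, dy = self.center_and_geometry()
        r = np.hypot(dx, dy)
        rs = np.where(r > 0, r, 1.0)
        f = make_field(3.0 * dx / rs, 3.0 * dy / rs)
        prof = radial_profile(f, (cx, cy))
        np.testing.assert_allclose(prof.value, 3.0, rtol=1e-12)

    def test_rigid_rotation_zero_radial(self):
        (cx, cy), dx, dy = self.center_and_geometry()
        f = make_field(-0.2 * dy, 0.2 * dx)
        prof = radial_profile(f, (cx, cy))
        np.testing.assert_allclose(prof.value, 0.0, atol=1e-12)

    def test_linear_radial_field_matches_brute_force(self):
        kappa = 0.1
        (cx, cy), dx, dy = self.center_and_geometry()
        f = make_field(kappa * dx, kappa * dy)
        bw = 10.0
        prof = radial_profile(f, (cx, cy), bin_width=bw)
        # independent per-node loop
        bins = {}
        for i in range(f.u.shape[0]):
            for j in range(f.u.shape[1]):
                r = np.hypot(dx[i, j], dy[i, j])
                if r == 0:
                    continue
                vr = (f.u[i, j] * dx[i, j] + f.v[i, j] * dy[i, j]) / r
                bins.setdefault(int(r // bw), []).append(vr)
        for rc, val in zip(prof.r_centers, prof.value):
            k = int(rc / bw)
            assert val == pytest.approx(np.mean(bins[k]), rel=1e-12)

    def test_masked_nodes_excluded(self):
        (cx, cy), dx, dy = self.center_and_geometry()
        r = np.hypot(dx, dy)
        rs = np.where(r > 0, r, 1.0)
        mask = np.ones_like(r, dtype=bool)
        mask[:, :5] = False
        f = make_field(2.0 * dx / rs, 2.0 * dy / rs, mask=mask)
        prof = radial_profile(f, (cx, cy))
        np.testing.assert_allclose(prof.value, 2.0, rtol=1e-12)
        assert prof.n.sum() == mask.sum() - 1  # center node skipped

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_linearity_property(self, seed):
        """profile(aF + bG) = a profile(F) + b profile(G) on a shared mask."""
        rng = np.random.default_rng(seed)
        shape = (9, 9)
        mask = rng.random(shape) > 0.2
        mask[4, 4] = True
        u1, v1, u2, v2 = rng.normal(size=(4, *shape))
        a, b = rng.normal(size=2)
        f1 = make_field(u1, v1, mask=mask.copy())
        f2 = make_field(u2, v2, mask=mask.copy())
        fc = make_field(a * u1 + b * u2, a * v1 + b * v2, mask=mask.copy())
        center = (40.0, 40.0)
        p1 = radial_profile(f1, center)
        p2 = radial_profile(f2, center)
        pc = radial_profile(fc, center)
        np.testing.assert_allclose(pc.value, a * p1.value + b * p2.value,
                                   rtol=1e-9, atol=1e-12)

    def test_bad_bin_width(self):
        f = uniform_field()
        with pytest.raises(ValueError):
            radial_profile(f, (0.0, 0.0), bin_width=0.0)


class TestSmoothProfiles:
    def make(self, vals):
        r = np.array([5.0, 15.0, 25.0])
        return profile_from_arrays(r, np.asarray(vals, dtype=float))

    def test_identical_profiles_idempotent(self):
        profs = [self.make([1.0, 2.0, 3.0])] * 5
        out = smooth_profiles(profs)
        np.testing.assert_allclose(out.value, [1.0, 2.0, 3.0])
        assert not out.short_window

    def test_mean_over_window(self):
        profs = [self.make([v, 0.0, 0.0]) for v in (1, 2, 3, 4, 5)]
        out = smooth_profiles(profs)
        assert out.value[0] == pytest.approx(3.0)
        assert out.n[0] == 5

    def test_short_window_flagged(self):
        out = smooth_profiles([self.make([1, 1, 1])] * 3, window=5)
        assert out.short_window

    def test_random_profiles_match_brute_force(self, rng):
        profs = [self.make(rng.normal(size=3)) for _ in range(5)]
        out = smooth_profiles(profs)
        expected = np.mean([p.value for p in profs], axis=0)
        np.testing.assert_allclose(out.value, expected, rtol=1e-12)

    def test_inconsistent_binning_raises(self):
        p1 = self.make([1, 2, 3])
        p2 = profile_from_arrays([4.0, 12.0, 20.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            smooth_profiles([p1, p2])

    def test_rolling_length_preserved(self):
        profs = [self.make([v, v, v]) for v in range(7)]
        out = rolling_smooth(profs, window=5)
        assert len(out) == 7
        assert out[0].short_window and not out[6].short_window
        assert out[6].value[0] == pytest.approx(np.mean([2, 3, 4, 5, 6]))


class TestOrderParameters:
    def test_uniform_field(self):
        ops = order_parameters(uniform_field(u0=3.0, v0=4.0))
        np.testing.assert_allclose(ops.v_cm, [3.0, 4.0])
        assert ops.v_rms == 0.0
        assert np.all(np.isclose(ops.alignment, 1.0))

    def test_antiparallel_pair_degenerate_cm(self):
        f = make_field(np.array([[2.0, -2.0]]), np.array([[0.0, 0.0]]))
        ops = order_parameters(f)
        np.testing.assert_allclose(ops.v_cm, [0.0, 0.0], atol=1e-15)
        assert ops.v_rms == pytest.approx(2.0)
        assert np.all(np.isnan(ops.alignment))

    def test_random_field_matches_brute_force(self, rng):
        u, v = rng.normal(size=(2, 10, 10))
        ops = order_parameters(make_field(u, v))
        v_cm = np.array([u.mean(), v.mean()])
        v_rms = np.sqrt(np.mean((u - v_cm[0]) ** 2 + (v - v_cm[1]) ** 2))
        assert ops.v_rms == pytest.approx(v_rms, rel=1e-12)
        ai = ops.alignment[5, 5]
        expected = (u[5, 5] * v_cm[0] + v[5, 5] * v_cm[1]) / (
            np.hypot(u[5, 5], v[5, 5]) * np.hypot(*v_cm))
        assert ai == pytest.approx(expected, rel=1e-12)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_permutation_and_shift_invariance(self, seed):
        """v_RMS is invariant under node permutation and constant boosts."""
        rng = np.random.default_rng(seed)
        u, v = rng.normal(size=(2, 6, 6))
        base = order_parameters(make_field(u, v))
        perm = rng.permutation(36)
        up = u.ravel()[perm].reshape(6, 6)
        vp = v.ravel()[perm].reshape(6, 6)
        assert order_parameters(make_field(up, vp)).v_rms == pytest.approx(
            base.v_rms, rel=1e-12)
        boost = order_parameters(make_field(u + 7.3, v - 2.1))
        assert boost.v_rms == pytest.approx(base.v_rms, rel=1e-9)

    def test_alignment_bounds(self, rng):
        u, v = rng.normal(size=(2, 12, 12))
        a = order_parameters(make_field(u, v)).alignment
        a = a[np.isfinite(a)]
        assert np.all((a >= -1.0) & (a <= 1.0))


class TestCorrelationLength:
    def test_uniform_field_flagged_non_decaying(self):
        fit = correlation_length(uniform_field(shape=(32, 32)), max_lag=100.0)
        assert not fit.converged
        np.testing.assert_allclose(fit.extra["corr"], 1.0)

    def test_exponential_field_round_trip(self):
        f = gen_correlated_field((256, 256), spacing=10.0, L0=100.0, seed=0)
        fit = correlation_length(f, max_lag=600.0)
        assert fit.converged
        assert fit.params["Lcorr"] == pytest.approx(100.0, rel=0.15)

    def test_white_noise_short_correlation(self, rng):
        f = make_field(*rng.normal(size=(2, 64, 64)))
        fit = correlation_length(f, max_lag=300.0)
        assert fit.converged
        assert fit.params["Lcorr"] <= 1.5 * 10.0  # 1.5 grid spacings
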