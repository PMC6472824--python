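import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from bumptraj import geometry
from bumptraj.binning import BIN_META_COLUMNS, BinnedPopulation
from bumptraj.geometry import (
    Trajectory,
    anchor_distances,
    distance_profile,
    fit_coefficients,
    fit_sinusoid,
    linear_speed,
    percentile_split,
    project,
    radius_variability,
    segment_radius,
)


def make_bins(n_segments, bins_per_seg, target=500.0, trial_id=0, bin_ms=None):
    bin_ms = target / bins_per_seg if bin_ms is None else bin_ms
    rows = []
    for seg in range(n_segments):
        for j in range(bins_per_seg):
            rows.append(
                (
                    trial_id, "SCT", target, 0, seg, j,
                    seg + (j + 0.5) / bins_per_seg,
                    seg * target + (j + 0.5) * bin_ms,
                    bin_ms,
                )
            )
    return pd.DataFrame(rows, columns=BIN_META_COLUMNS)


def make_traj(Y, n_segments, bins_per_seg, target=500.0, trial_id=0):
    return Trajectory(
        Y=np.asarray(Y, dtype=float),
        bins=make_bins(n_segments, bins_per_seg, target, trial_id),
        n_components=np.asarray(Y).shape[1],
    )


def circle_points(n, radius=1.0, center=(0.0, 0.0), phase=0.0):
    theta = 2 * np.pi * np.arange(n) / n + phase
    return np.column_stack(
        [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)]
    )


def make_binned(X, bins_per_seg=50, target=500.0):
    X = np.asarray(X, dtype=float)
    n_segments = X.shape[1] // bins_per_seg
    return BinnedPopulation(
        X=X,
        neuron_ids=np.arange(X.shape[0]),
        bins=make_bins(n_segments, bins_per_seg, target),
        mode="utnd",
    )


class TestFitCoefficients:
    def test_orthonormal_and_ordered(self, rng):
        X = rng.normal(size=(12, 100))
        coeffs = fit_coefficients(make_binned(X))
        PPt = coeffs.P @ coeffs.P.T
        assert np.allclose(PPt, np.eye(PPt.shape[0]), atol=1e-8)
        evr = coeffs.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)

    def test_planted_rank2_plane_recovered(self, rng):
        # two orthogonal oscillatory modes, no noise: the leading pair must
        # span the planted plane (oracle: principal angles vs construction)
        t = np.linspace(0, 4 * np.pi, 200)
        u = np.zeros(10)
        v = np.zeros(10)
        u[0], v[1] = 1.0, 1.0
        X = np.outer(u, np.sin(t)) + np.outer(v, np.cos(t))
        coeffs = fit_coefficients(make_binned(X))
        from scipy.linalg import subspace_angles

        planted = np.column_stack([u, v])
        angles = subspace_angles(coeffs.P[:2].T, planted)
        assert np.max(angles) < 1e-6

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_coefficients(make_binned(np.zeros((5, 100))))

    def test_too_few_bins_rejected(self):
        X = np.ones((4, 1))
        binned = BinnedPopulation(
            X=X, neuron_ids=np.arange(4), bins=make_bins(1, 1), mode="utnd"
        )
        with pytest.raises(ValueError, match="at least 2 bins"):
            fit_coefficients(binned)


class TestProject:
    def test_training_scores_reproduced(self, rng):
        X = rng.normal(size=(8, 100))
        binned = make_binned(X)
        coeffs = fit_coefficients(binned, n_retained=5)
        traj = project(coeffs, binned)
        from sklearn.decomposition import PCA

        ref = PCA(n_components=5, svd_solver="full").fit(X.T)
        expected = ref.transform(X.T)
        # components are sign-ambiguous; compare up to per-column sign
        for c in range(5):
            assert np.allclose(traj.Y[:, c], expected[:, c], atol=1e-8) or np.allclose(
                traj.Y[:, c], -expected[:, c], atol=1e-8
            )

    def test_neuron_mismatch_rejected(self, rng):
        X = rng.normal(size=(8, 100))
        binned = make_binned(X)
        coeffs = fit_coefficients(binned)
        other = make_binned(X[:6])
        with pytest.raises(ValueError, match="mismatch"):
            project(coeffs, other)

    def test_identical_rates_identical_trajectories(self, rng):
        X = rng.normal(size=(8, 100))
        binned = make_binned(X)
        coeffs = fit_coefficients(binned)
        a = project(coeffs, binned)
        b = project(coeffs, binned)
        assert np.array_equal(a.Y, b.Y)

    def test_smoothing_bounded_by_local_spread(self, rng):
        X = rng.normal(size=(6, 100))
        binned = make_binned(X)
        coeffs = fit_coefficients(binned, n_retained=3)
        raw = project(coeffs, binned, smooth=False)
        smooth = project(coeffs, binned, smooth=True, smooth_span=0.1)
        span = max(int(0.1 * 50), 3)
        for c in range(3):
            y = raw.Y[:, c]
            # oracle bound: a local regression cannot leave the local range
            local_spread = max(
                y[max(0, i - span) : i + span + 1].max()
                - y[max(0, i - span) : i + span + 1].min()
                for i in range(len(y))
            )
            assert np.max(np.abs(smooth.Y[:, c] - y)) <= local_spread + 1e-9


class TestSegmentRadius:
    def test_circle_exact(self):
        pts = circle_points(60, radius=2.0, center=(5.0, -3.0))
        traj = make_traj(pts, 1, 60)
        geom = segment_radius(traj, 0, 0, components=(0, 1))
        assert geom.radius == pytest.approx(2.0, abs=1e-12)

    def test_identical_points_radius_zero_with_warning(self):
        pts = np.ones((10, 2))
        traj = make_traj(pts, 1, 10)
        with pytest.warns(UserWarning, match="degenerate"):
            geom = segment_radius(traj, 0, 0, components=(0, 1))
        assert geom.radius == 0.0

    def test_ellipse_matches_quadrature_oracle(self):
        # unit-speed ellipse semi-axes 2 and 1: mean center distance by
        # dense arc-length quadrature
        a, b = 2.0, 1.0
        theta = np.linspace(0, 2 * np.pi, 20001)
        x, y = a * np.cos(theta), b * np.sin(theta)
        speed = np.hypot(-a * np.sin(theta), b * np.cos(theta))
        r = np.hypot(x, y)
        expected = integrate.trapezoid(r * speed, theta) / integrate.trapezoid(speed, theta)
        # sample the ellipse uniformly in arc length for the implementation
        arc = integrate.cumulative_trapezoid(speed, theta, initial=0.0)
        s_uniform = np.linspace(0, arc[-1], 2000, endpoint=False)
        th = np.interp(s_uniform, arc, theta)
        pts = np.column_stack([a * np.cos(th), b * np.sin(th)])
        traj = make_traj(pts, 1, 2000)
        geom = segment_radius(traj, 0, 0, components=(0, 1))
        assert geom.radius == pytest.approx(expected, rel=1e-3)

    def test_short_segment_rejected(self):
        traj = make_traj(np.ones((2, 2)), 1, 2)
        with pytest.raises(ValueError, match="at least 3"):
            segment_radius(traj, 0, 0, components=(0, 1))


class TestRadiusVariability:
    def test_six_identical_circles_zero(self):
        geoms = []
        pts = circle_points(50, radius=1.5)
        for seg in range(6):
            traj = make_traj(pts, 1, 50)
            geoms.append(segment_radius(traj, 0, 0, components=(0, 1)))
        assert radius_variability(geoms) == pytest.approx(0.0, abs=1e-12)

    def test_radius_spread_recovered(self, rng):
        # circles with radii drawn around a mean with SD sigma: pooled SD of
        # centroid distances approaches sigma at dense sampling
        sigma = 0.3
        radii = 2.0 + sigma * rng.standard_normal(200)
        geoms = []
        for r in radii:
            pts = circle_points(50, radius=abs(r))
            traj = make_traj(pts, 1, 50)
            geoms.append(segment_radius(traj, 0, 0, components=(0, 1)))
        est = radius_variability(geoms, expected_segments=1)
        assert est == pytest.approx(np.std(np.abs(radii)), rel=0.05)

    def test_methods_and_errors(self):
        pts = circle_points(30)
        traj = make_traj(pts, 1, 30)
        g = segment_radius(traj, 0, 0, components=(0, 1))
        with pytest.warns(UserWarning, match="variability"):
            radius_variability([g])
        assert radius_variability([g, g], method="radii", expected_segments=2) == 0.0
        with pytest.raises(ValueError):
            radius_variability([])
        with pytest.raises(ValueError):
            radius_variability([g], method="bogus", expected_segments=1)


class TestLinearSpeed:
    def test_stationary_zero(self):
        traj = make_traj(np.ones((20, 3)), 1, 20)
        assert linear_speed(traj, 0, 0) == pytest.approx(0.0)

    def test_uniform_circular_motion(self):
        # radius R, period T sampled at 20 ms: speed ~ 2*pi*R/T
        R, T, bin_ms = 2.0, 1000.0, 20.0
        n = int(T / bin_ms)
        pts = np.column_stack([circle_points(n, radius=R), np.zeros(n)])
        traj = Trajectory(
            Y=pts, bins=make_bins(1, n, target=T, bin_ms=bin_ms), n_components=3
        )
        expected = 2 * np.pi * R / T
        assert linear_speed(traj, 0, 0) == pytest.approx(expected, rel=0.01)

    def test_single_bin_rejected(self):
        traj = make_traj(np.ones((1, 3)), 1, 1)
        with pytest.raises(ValueError):
            linear_speed(traj, 0, 0)


class TestPercentileSplit:
    def test_coupled_radius_duration(self, rng):
        produced = rng.uniform(400, 500, 100)
        radii = 0.01 * produced + rng.normal(0, 0.01, 100)
        targets = np.full(100, 450.0)
        out = percentile_split(radii, produced, targets)
        assert out["short_mean_radius"].iloc[0] < out["long_mean_radius"].iloc[0]

    def test_planted_linear_coupling_slope(self, rng):
        # radius = s * duration: group difference ~ s * (mean long - mean short)
        s = 0.002
        produced = rng.uniform(800, 1200, 400)
        radii = s * produced
        targets = np.full(400, 1000.0)
        out = percentile_split(radii, produced, targets)
        lo = produced[produced < np.percentile(produced, 20)]
        hi = produced[produced > np.percentile(produced, 80)]
        expected = s * (hi.mean() - lo.mean())
        got = out["long_mean_radius"].iloc[0] - out["short_mean_radius"].iloc[0]
        assert got == pytest.approx(expected, rel=1e-9)

    def test_identical_produced_intervals_degenerate(self):
        radii = np.ones(20)
        produced = np.full(20, 500.0)
        targets = np.full(20, 500.0)
        out = percentile_split(radii, produced, targets)
        assert out["n_short"].iloc[0] == 0
        assert out["n_long"].iloc[0] == 0

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            percentile_split(np.ones(5), np.ones(5), np.ones(5))


class TestFitSinusoid:
    def test_exact_recovery_without_detrend(self):
        t = np.arange(30) / 30
        y = 0.5 * np.sin(2 * np.pi * t + 1.0) + 0.2
        fit = fit_sinusoid(y, detrend=False)
        assert fit.amplitude == pytest.approx(0.5, abs=1e-6)
        assert fit.phase == pytest.approx(1.0, abs=1e-6)
        assert fit.offset == pytest.approx(0.2, abs=1e-6)
        assert fit.mse < 1e-12

    def test_detrended_fit_matches_linear_oracle(self):
        # after detrending, the model is linear in (sin, cos, 1); the
        # nonlinear fit must land on the least-squares solution
        t = np.arange(30) / 30
        y = 0.5 * np.sin(2 * np.pi * t + 1.0) + 0.2
        fit = fit_sinusoid(y, detrend=True)
        slope, intercept = np.polyfit(t, y, 1)
        resid = y - (slope * t + intercept)
        A = np.column_stack([np.sin(2 * np.pi * t), np.cos(2 * np.pi * t), np.ones(30)])
        coef, *_ = np.linalg.lstsq(A, resid, rcond=None)
        a_exp = np.hypot(coef[0], coef[1])
        c_exp = np.mod(np.arctan2(coef[1], coef[0]), 2 * np.pi)
        assert fit.amplitude == pytest.approx(a_exp, abs=1e-6)
        assert fit.phase == pytest.approx(c_exp, abs=1e-5)
        assert abs(fit.offset - coef[2]) < 1e-6
        # detrending a pure sinusoid keeps the fit in the right ballpark
        assert fit.amplitude == pytest.approx(0.5, abs=0.15)
        assert fit.phase == pytest.approx(1.0, abs=0.4)

    def test_noise_mse_calibrated(self, rng):
        # sinusoid + N(0, 0.1): MSE ~ 0.01 (Monte-Carlo oracle)
        mses = []
        for _ in range(200):
            t = np.arange(30) / 30
            y = np.sin(2 * np.pi * t) + rng.normal(0, 0.1, 30)
            mses.append(fit_sinusoid(y, detrend=False).mse)
        assert np.mean(mses) == pytest.approx(0.01, rel=0.2)

    def test_canonical_form(self):
        t = np.arange(30) / 30
        y = -0.7 * np.sin(2 * np.pi * t + 0.3)
        fit = fit_sinusoid(y, detrend=False)
        assert fit.amplitude >= 0
        assert 0 <= fit.phase < 2 * np.pi
        assert fit.amplitude == pytest.approx(0.7, abs=1e-6)


class TestAnchorDistances:
    def test_tangent_circles(self):
        # circles of different radii sharing the point (0, 0); anchor there
        radii = [1.0, 1.5, 2.0, 2.5]
        tap_pts = np.zeros((len(radii), 2))
        half_pts = np.array([[2 * r, 0.0] for r in radii])
        anchor, d_tap, d_half = anchor_distances(tap_pts, half_pts)
        assert np.allclose(anchor, [0.0, 0.0])
        assert np.allclose(d_tap, 0.0)
        assert np.allclose(d_half, [2 * r for r in radii])

    def test_radius_linear_in_target_gives_dhalf_slope_2beta(self):
        # tangent circles with r(T) = alpha + beta*T: d_half = 2r, so the
        # d_half-vs-T slope is 2*beta (analytic geometry oracle)
        alpha, beta = 0.5, 0.002
        targets = np.array([450.0, 550.0, 650.0, 850.0, 1000.0])
        rows = []
        for T in targets:
            r = alpha + beta * T
            n = 40
            pts = circle_points(n, radius=r, center=(r, 0.0), phase=np.pi)
            rows.append(pts)
        Y = np.vstack(rows)
        bins = pd.concat(
            [make_bins(1, 40, target=T, trial_id=i) for i, T in enumerate(targets)],
            ignore_index=True,
        )
        traj = Trajectory(Y=Y, bins=bins, n_components=2)
        res = geometry.anchor_distance_analysis(traj, components=(0, 1))
        assert res.d_half_regression.slope == pytest.approx(2 * beta, rel=1e-6)
        assert abs(res.d_tap_regression.slope) < 1e-9

    def test_optimize_rule_runs(self, rng):
        pts = circle_points(40, radius=1.0)
        traj = make_traj(pts, 1, 40)
        res = geometry.anchor_distance_analysis(traj, components=(0, 1), anchor_rule="optimize")
        assert res.table.shape[0] == 1
        with pytest.raises(ValueError):
            geometry.anchor_distance_analysis(traj, components=(0, 1), anchor_rule="bogus")


class TestDistanceProfile:
    def test_self_distance_zero(self):
        pts = circle_points(40)
        traj = make_traj(np.column_stack([pts, np.zeros(40)]), 1, 40)
        dist, summary = distance_profile(traj, traj)
        assert np.allclose(dist, 0.0)
        assert summary["mean_distance"].iloc[0] == 0.0

    def test_concentric_circles_constant_gap(self):
        r1, r2 = 1.0, 2.5
        a = make_traj(np.column_stack([circle_points(60, r1), np.zeros(60)]), 1, 60)
        b = make_traj(np.column_stack([circle_points(60, r2), np.zeros(60)]), 1, 60)
        dist, summary = distance_profile(a, b, n_bins=60)
        assert np.allclose(dist, r2 - r1, atol=1e-9)
        assert summary["sd_distance"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_segment_count_mismatch_rejected(self):
        a = make_traj(np.ones((20, 2)), 1, 20)
        b = make_traj(np.ones((40, 2)), 2, 20)
        with pytest.raises(ValueError, match="segment count"):
            distance_profile(a, b, components=(0, 1))


class TestRotationInvariance:
    def test_geometry_invariant_under_rotation(self, rng):
        from scipy.stats import ortho_group

        Y = rng.normal(size=(60, 3))
        traj = make_traj(Y, 2, 30)
        R = ortho_group.rvs(3, random_state=rng)
        rotated = make_traj(Y @ R.T, 2, 30)
        for seg in (0, 1):
            g1 = segment_radius(traj, 0, seg, components=(0, 1, 2))
            g2 = segment_radius(rotated, 0, seg, components=(0, 1, 2))
            assert g1.radius == pytest.approx(g2.radius, abs=1e-10)
            s1 = linear_speed(traj, 0, seg)
            s2 = linear_speed(rotated, 0, seg)
            assert s1 == pytest.approx(s2, abs=1e-10)
        d1, _ = distance_profile(traj, traj)
        d2, _ = distance_profile(rotated, rotated)
        assert np.allclose(d1, d2, atol=1e-10)
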