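"""Trajectory linking, MSD/diffusion, line-deviation FWHM, registration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ucnpkit import tracking
from ucnpkit.tracking import (
    FWHM_FACTOR,
    MSDCurve,
    Trajectory,
    compute_msd,
    estimate_diffusion,
    fit_affine_registration,
    line_deviation_fwhm,
    link_localizations,
    match_points,
)
from ucnpkit.synthetic import MotionTruth, generate_trajectory


def make_locs(tracks):
    """tracks: list of (n, 2) arrays, one row per frame."""
    rows = []
    for pts in tracks:
        for f, (x, y) in enumerate(pts):
            rows.append({"frame": f, "x": x, "y": y})
    return pd.DataFrame(rows)


class TestLinking:
    def test_single_emitter_full_track(self):
        pts = np.cumsum(np.full((30, 2), 5.0), axis=0)
        trajs = link_localizations(make_locs([pts]), max_disp=20.0)
        assert len(trajs) == 1
        assert len(trajs[0]) == 30

    def test_two_distant_emitters_never_switch(self):
        a = np.zeros((20, 2))
        b = np.full((20, 2), 1e5)
        trajs = link_localizations(make_locs([a, b]), max_disp=50.0)
        assert len(trajs) == 2
        for t in trajs:
            assert np.ptp(t.positions, axis=0).max() == 0.0

    def test_known_identities_linked_correctly(self):
        """Five well-separated Brownian walkers: ≥99% of links correct."""
        rng = np.random.default_rng(5)
        tracks = []
        for i in range(5):
            origin = np.array([i * 5000.0, 0.0])
            steps = rng.normal(0, 30.0, (100, 2))
            tracks.append(origin + np.cumsum(steps, axis=0))
        trajs = link_localizations(make_locs(tracks), max_disp=300.0)
        assert len(trajs) == 5
        n_links = sum(len(t) - 1 for t in trajs)
        correct = 0
        for t in trajs:
            truth = min(tracks, key=lambda tr: np.linalg.norm(tr[0] - t.positions[0]))
            correct += int(np.sum(np.all(np.isclose(t.positions, truth), axis=1))) - 1
        assert correct / n_links >= 0.99

    def test_gap_bridging(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [30.0, 0.0]])
        locs = pd.DataFrame(
            {"frame": [0, 1, 3], "x": pts[:, 0], "y": pts[:, 1]}
        )
        trajs = link_localizations(locs, max_disp=50.0, max_gap=1)
        assert len(trajs) == 1 and len(trajs[0]) == 3
        trajs = link_localizations(locs, max_disp=50.0, max_gap=0)
        assert max(len(t) for t in trajs) == 2


class TestMSD:
    def test_uniform_linear_motion_quadratic(self):
        v = 120.0  # nm/s
        t = np.arange(40) * 0.1
        traj = Trajectory(times=t, positions=np.column_stack([v * t, np.zeros_like(t)]))
        msd = compute_msd(traj, max_lag_fraction=0.5)
        np.testing.assert_allclose(msd.msd, v**2 * msd.lags**2, rtol=1e-12)

    def test_counts_nonincreasing(self):
        traj, _ = generate_trajectory(MotionTruth("brownian", D=0.01), n=100, seed=0)
        msd = compute_msd(traj)
        assert np.all(np.diff(msd.counts) <= 0)

    def test_static_emitter_offset_is_4_sigma_squared(self):
        sigma = 15.0
        traj, _ = generate_trajectory(
            MotionTruth("brownian", D=0.0), n=20000, loc_noise=sigma, seed=8
        )
        msd = compute_msd(traj, max_lag_fraction=0.001)
        np.testing.assert_allclose(msd.msd, 4 * sigma**2, rtol=0.05)

    def test_time_reversal_symmetry(self):
        traj, _ = generate_trajectory(MotionTruth("brownian", D=0.02), n=64, seed=3)
        rev = Trajectory(times=traj.times, positions=traj.positions[::-1].copy())
        a, b = compute_msd(traj), compute_msd(rev)
        np.testing.assert_allclose(a.msd, b.msd, rtol=1e-12)

    def test_short_trajectory_rejected(self):
        t = np.arange(5) * 0.1
        with pytest.raises(ValueError):
            compute_msd(Trajectory(times=t, positions=np.zeros((5, 2))))


class TestDiffusion:
    def test_exact_line_recovers_D(self):
        D_um = 0.02
        lags = np.arange(1, 8) * 0.1
        msd = MSDCurve(lags=lags, msd=4 * D_um * 1e6 * lags, counts=np.full(7, 50))
        est = estimate_diffusion(msd)
        assert est.D == pytest.approx(D_um, rel=1e-12)
        assert est.intercept == pytest.approx(0.0, abs=1e-9)

    def test_offset_absorbed_by_intercept(self):
        D_um, sigma = 0.05, 20.0
        lags = np.arange(1, 6) * 0.1
        msd = MSDCurve(
            lags=lags, msd=4 * D_um * 1e6 * lags + 4 * sigma**2, counts=np.full(5, 9)
        )
        est = estimate_diffusion(msd)
        assert est.D == pytest.approx(D_um, rel=1e-12)
        assert est.intercept == pytest.approx(4 * sigma**2, rel=1e-9)

    def test_brownian_ensemble_recovery(self):
        """10 fps imaging of D = 0.0186 µm²/s Brownian motion: the ensemble
        mean estimate covers the truth."""
        D = 0.0186
        ests = []
        for seed in range(40):
            traj, _ = generate_trajectory(
                MotionTruth("brownian", D=D), dt=0.1, n=600, loc_noise=15.0, seed=seed
            )
            ests.append(estimate_diffusion(compute_msd(traj)).D)
        ests = np.asarray(ests)
        ci = 1.96 * ests.std(ddof=1) / np.sqrt(ests.size)
        assert abs(ests.mean() - D) < ci + 0.1 * D


class TestLineDeviation:
    def test_collinear_points_zero_width(self):
        t = np.linspace(0, 1, 50)
        pts = np.column_stack([3 * t + 1, -2 * t + 5])
        assert line_deviation_fwhm(pts) == 0.0

    def test_gaussian_scatter_fwhm_identity(self):
        """σ_t = 98 nm transverse scatter ⇒ FWHM ≈ 2.355·98 ≈ 231 nm."""
        sigma_t = 98.0
        traj, _ = generate_trajectory(
            MotionTruth("directed", v=500.0, direction=0.4, sigma_t=sigma_t),
            n=2000, seed=2,
        )
        fwhm = line_deviation_fwhm(traj.positions)
        assert fwhm == pytest.approx(FWHM_FACTOR * sigma_t, rel=0.05)
        assert fwhm == pytest.approx(231.0, rel=0.06)

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(angle=st.floats(0.0, 2 * np.pi))
    def test_rotation_invariance(self, angle):
        rng = np.random.default_rng(11)
        t = np.linspace(0, 1000, 400)
        pts = np.column_stack([t, rng.normal(0, 50.0, t.size)])
        R = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        assert line_deviation_fwhm(pts @ R.T) == pytest.approx(
            line_deviation_fwhm(pts), rel=1e-6
        )


class TestRegistration:
    def test_identity_mapping(self):
        pts = np.random.default_rng(0).random((10, 2)) * 100
        amap = fit_affine_registration(pts, pts)
        assert amap.a == pytest.approx((0.0, 1.0, 0.0), abs=1e-9)
        assert amap.b == pytest.approx((0.0, 0.0, 1.0), abs=1e-9)
        assert amap.rms_residual < 1e-9

    def test_known_affine_recovered_exactly(self):
        rng = np.random.default_rng(1)
        src = rng.random((25, 2)) * 1000
        theta, scale, shift = np.deg2rad(30.0), 1.2, np.array([50.0, -20.0])
        R = scale * np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        dst = src @ R.T + shift
        amap = fit_affine_registration(src, dst)
        np.testing.assert_allclose(amap.matrix, R, atol=1e-9)
        np.testing.assert_allclose(amap.apply(src), dst, atol=1e-6)

    def test_collinear_points_rejected(self):
        src = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.raises(np.linalg.LinAlgError):
            fit_affine_registration(src, src)

    def test_residual_noise_scaling(self):
        """rms residual ≈ σ·√(2(n−3)/n) for isotropic target noise."""
        sigma, n = 4.0, 40
        rms = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            src = rng.random((n, 2)) * 500
            dst = src + rng.normal(0, sigma, (n, 2))
            rms.append(fit_affine_registration(src, dst).rms_residual)
        expected = sigma * np.sqrt(2 * (n - 3) / n)
        assert np.mean(rms) == pytest.approx(expected, rel=0.1)

    def test_rigid_transform_invariance_of_residual(self):
        rng = np.random.default_rng(4)
        src = rng.random((20, 2)) * 100
        dst = src + rng.normal(0, 2.0, (20, 2))
        base = fit_affine_registration(src, dst).rms_residual
        theta = 0.7
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moved = fit_affine_registration(src @ R.T + 30.0, dst @ R.T + 30.0)
        assert moved.rms_residual == pytest.approx(base, rel=1e-9)


class TestMatchPoints:
    def test_identical_sets_fully_matched(self):
        pts = np.random.default_rng(2).random((30, 2)) * 100
        matches, un_s, un_d = match_points(pts, pts)
        assert len(matches) == 30
        assert len(un_s) == len(un_d) == 0
        np.testing.assert_array_equal(matches[:, 0], matches[:, 1])

    def test_affine_with_outliers(self):
        rng = np.random.default_rng(6)
        src = rng.random((50, 2)) * 1000
        theta = 0.2
        R = 1.1 * np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        dst = src @ R.T + np.array([10.0, 5.0])
        outliers = rng.random((5, 2)) * 1000
        dst_all = np.vstack([dst, outliers])
        amap = fit_affine_registration(src, dst)
        matches, _, _ = match_points(src, dst_all, initial_map=amap)
        correct = np.mean(matches[:, 0] == matches[:, 1])
        assert len(matches) >= 0.95 * 50
        assert correct >= 0.95

    def test_disjoint_far_sets_unmatched(self):
        a = np.random.default_rng(0).random((10, 2))
        b = a + 1e6
        matches, un_s, un_d = match_points(a, b)
        assert len(matches) == 0
        assert len(un_s) == 10 and len(un_d) == 10
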