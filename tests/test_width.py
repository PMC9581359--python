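"""Section PCA, confidence scaling, mean ellipse radius, and W_obs(s, φ)."""

import numpy as np
import pytest
from hypothesis import given, strategies as hst
from scipy import stats as sps
from scipy.integrate import quad
from scipy.spatial.transform import Rotation

import stochid as st
from stochid.errors import InsufficientSamplesError, ProfileError
from stochid.geometry import PlaneCrossing
from conftest import straight_tube_spec


def _crossing(points2d, tangent=(0.0, 0.0, 1.0), center=(0.0, 0.0, 0.0)):
    tangent = np.asarray(tangent, float)
    tangent = tangent / np.linalg.norm(tangent)
    from stochid.width import _in_plane_basis
    basis = _in_plane_basis(tangent)
    pts3 = np.asarray(center, float) + np.asarray(points2d, float) @ basis
    ids = tuple(f"t{i}" for i in range(len(pts3)))
    return PlaneCrossing(0, pts3, ids, ()), tangent


class TestPlanePCA:
    def test_collinear_points_give_sigma_1_0(self):
        cr, tan = _crossing([[1.0, 0.0], [-1.0, 0.0], [0.0, 0.0]])
        stats = st.plane_pca(cr, tan)
        assert stats.sigma_eps == pytest.approx(1.0, abs=1e-12)
        assert stats.sigma_eta == pytest.approx(0.0, abs=1e-12)
        assert stats.n_used == 3

    def test_isotropic_sample_recovers_sigma(self):
        rng = np.random.default_rng(1234)
        sigma = 3.0
        cr, tan = _crossing(rng.normal(scale=sigma, size=(10_000, 2)))
        stats = st.plane_pca(cr, tan)
        assert stats.sigma_eps == pytest.approx(sigma, rel=0.03)
        assert stats.sigma_eta == pytest.approx(sigma, rel=0.03)

    def test_rigid_rotation_rotates_axes_not_sigmas(self):
        rng = np.random.default_rng(7)
        pts2 = rng.normal(size=(40, 2)) * [4.0, 1.5]
        cr, tan = _crossing(pts2)
        ref = st.plane_pca(cr, tan)
        rot = Rotation.from_rotvec([0.3, -0.5, 0.9]).as_matrix()
        cr2 = PlaneCrossing(0, cr.q @ rot.T, cr.trial_ids, ())
        out = st.plane_pca(cr2, rot @ tan)
        assert out.sigma_eps == pytest.approx(ref.sigma_eps, abs=1e-9)
        assert out.sigma_eta == pytest.approx(ref.sigma_eta, abs=1e-9)
        np.testing.assert_allclose(np.abs(out.axes @ (rot @ ref.axes.T)),
                                   np.eye(2), atol=1e-9)

    def test_axes_orthogonal_to_tangent(self):
        rng = np.random.default_rng(2)
        cr, tan = _crossing(rng.normal(size=(15, 2)), tangent=(1.0, 2.0, 3.0))
        stats = st.plane_pca(cr, tan)
        np.testing.assert_allclose(stats.axes @ tan, 0.0, atol=1e-9)

    def test_single_point_insufficient(self):
        cr, tan = _crossing([[0.0, 0.0]])
        with pytest.raises(InsufficientSamplesError):
            st.plane_pca(cr, tan)

    def test_center_mode_mean_path_point_uses_given_center(self):
        # points offset from the plane centre: second moments about the
        # centre exceed the centroid-centred ones
        cr, tan = _crossing([[5.0, 1.0], [5.0, -1.0], [5.0, 0.0]])
        about_centroid = st.plane_pca(cr, tan, center_mode="centroid")
        about_center = st.plane_pca(cr, tan, center_mode="mean_path_point",
                                    center=np.zeros(3))
        assert about_centroid.sigma_eps == pytest.approx(1.0, abs=1e-12)
        assert about_center.sigma_eps > 5.0


class TestConfidenceScale:
    def test_hotelling_n7_reproduces_tabled_values(self):
        cs = st.c_squared(7, 0.95)
        assert cs.regime == "hotelling"
        assert (cs.nu1, cs.nu2) == (2, 5)
        assert sps.f.ppf(0.95, 2, 5) == pytest.approx(5.786, abs=5e-4)
        assert cs.c2 == pytest.approx(1.984, abs=5e-4)

    def test_population_regime_is_chi2_quantile(self):
        cs = st.c_squared(7, 0.95, population_known=True)
        assert cs.regime == "chi2"
        assert cs.c2 == pytest.approx(5.992, abs=1e-3)

    @given(hst.floats(min_value=0.01, max_value=0.98))
    def test_monotone_in_phi(self, phi):
        lo = st.c_squared(7, phi).c2
        hi = st.c_squared(7, phi + 0.01).c2
        assert 0.0 < lo < hi

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            st.c_squared(2, 0.95)

    @pytest.mark.parametrize("phi", [0.0, 1.0, -0.1, 1.5])
    def test_phi_out_of_range_rejected(self, phi):
        with pytest.raises(ValueError):
            st.c_squared(7, phi)


class TestMeanRadius:
    def test_circle_closed_form(self):
        c2 = 1.984
        assert st.mean_radius(2.5, 2.5, c2) == pytest.approx(np.sqrt(c2) * 2.5, rel=1e-12)

    def test_degenerate_closed_form(self):
        c2 = 1.984
        expected = (2 / np.pi) * np.sqrt(c2) * 3.0
        assert st.mean_radius(3.0, 0.0, c2) == pytest.approx(expected, rel=1e-12)

    def test_general_case_matches_adaptive_quadrature(self):
        se, sh, c2 = 3.0, 1.0, 1.984
        c = np.sqrt(c2)
        oracle, _ = quad(lambda th: c * np.hypot(se * np.cos(th), sh * np.sin(th)),
                         0.0, 2 * np.pi, epsabs=1e-13, epsrel=1e-13)
        oracle /= 2 * np.pi
        assert st.mean_radius(se, sh, c2) == pytest.approx(oracle, rel=1e-9)

    @given(hst.floats(min_value=0.5, max_value=10.0),
           hst.floats(min_value=0.2, max_value=1.0),
           hst.floats(min_value=0.5, max_value=8.0))
    def test_bounds_and_monotonicity(self, se, ratio, c2):
        sh = ratio * se
        r = st.mean_radius(se, sh, c2)
        c = np.sqrt(c2)
        assert c * sh - 1e-12 <= r <= c * se + 1e-12
        assert st.mean_radius(se * 1.1, sh, c2) >= r
        assert st.mean_radius(se, min(sh * 1.1, se), c2) >= r - 1e-12
        assert st.mean_radius(se, sh, c2 * 1.2) >= r

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            st.mean_radius(-1.0, 0.5, 1.0)
        with pytest.raises(ValueError):
            st.mean_radius(1.0, 0.5, 0.0)


class TestWidthProfile:
    def test_straight_isotropic_tube_matches_closed_form(self):
        """Constant isotropic σ = 2 mm noise around a straight path, n = 200,
        population regime: W should sit at 2·√χ²(2, .95)·σ along the interior."""
        spec = straight_tube_spec(sigma_eps=2.0, sigma_eta=2.0, n=200, seed=9)
        path = st.make_mean_path(spec)
        ens = st.simulate_trials(path, spec)
        grid = st.mean_path(ens, 100)
        wp = st.width_profile(ens, grid, phi=0.95, regime="chi2")
        expected = 2 * np.sqrt(sps.chi2.ppf(0.95, 2)) * 2.0
        rel = wp.W[10:90] / expected - 1.0
        # per-plane estimates carry ~4% sampling noise at n=200, so the
        # check is on the profile: RMS and mean within 5%
        assert np.sqrt(np.mean(rel ** 2)) < 0.05
        assert abs(np.mean(rel)) < 0.05

    def test_zero_noise_ensemble_is_profile_error(self):
        spec = straight_tube_spec(sigma_eps=0.0, sigma_eta=0.0, n=5, seed=0)
        path = st.make_mean_path(spec)
        ens = st.simulate_trials(path, spec)
        grid = st.mean_path(ens, 50)
        with pytest.raises(ProfileError):
            st.width_profile(ens, grid)

    def test_doubling_noise_doubles_width(self):
        widths = {}
        for scale in (1.0, 2.0):
            spec = straight_tube_spec(sigma_eps=2.0 * scale, sigma_eta=1.0 * scale,
                                      n=50, seed=31)
            path = st.make_mean_path(spec)
            ens = st.simulate_trials(path, spec)
            grid = st.mean_path(ens, 80)
            widths[scale] = st.width_profile(ens, grid).W[8:72]
        np.testing.assert_allclose(widths[2.0] / widths[1.0], 2.0, rtol=0.05)

    def test_scale_equivariance(self, default_ensemble):
        _, _, ens = default_ensemble
        lam = 3.5
        scaled = st.TrialEnsemble(ens.subject, ens.condition, [
            st.Trajectory(tr.trial_id, tr.t, tr.points * lam) for tr in ens])
        w1 = st.width_profile(ens, st.mean_path(ens, 60)).W
        w2 = st.width_profile(scaled, st.mean_path(scaled, 60)).W
        np.testing.assert_allclose(w2, lam * w1, rtol=1e-6)

    def test_rigid_motion_invariance(self, default_ensemble):
        _, _, ens = default_ensemble
        rot = Rotation.from_rotvec([0.4, 0.2, -0.7]).as_matrix()
        shift = np.array([12.0, -40.0, 5.0])
        moved = st.TrialEnsemble(ens.subject, ens.condition, [
            st.Trajectory(tr.trial_id, tr.t, tr.points @ rot.T + shift) for tr in ens])
        w1 = st.width_profile(ens, st.mean_path(ens, 60)).W
        w2 = st.width_profile(moved, st.mean_path(moved, 60)).W
        np.testing.assert_allclose(w2, w1, rtol=1e-6)

    def test_grid_and_flags_shape(self, default_ensemble):
        _, _, ens = default_ensemble
        grid = st.mean_path(ens, 60)
        wp = st.width_profile(ens, grid)
        assert wp.s.shape == wp.W.shape == wp.valid.shape == (60,)
        np.testing.assert_array_equal(wp.s, grid.s)
        assert (wp.W[wp.valid] > 0).all()
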