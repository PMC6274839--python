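"""Correlation profiles, persistence-length fits, stiffness, flexibility."""

import math

import numpy as np
import pytest

import coilflex as cf
from coilflex.axis import AxisPolyline
from conftest import random_rotation


def _axis_from_tangents(tangents, spacing=1.5):
    """AxisPolyline with given tangents and uniform arc spacing."""
    t = np.asarray(tangents, dtype=float)
    F, n, _ = t.shape
    vertices = np.concatenate(
        [np.zeros((F, 1, 3)), np.cumsum(spacing * t, axis=1)], axis=1
    )
    return AxisPolyline(
        vertices=vertices,
        tangents=t,
        mean_segment_lengths=np.full(n, spacing),
        arc_s=np.arange(n) * spacing,
    )


def _exact_profile(s, lp):
    """Synthetic profile lying exactly on the exponential law."""
    s = np.asarray(s, dtype=float)
    return cf.CorrelationProfile(
        s=s, c=np.exp(-s / lp), sem=np.zeros_like(s), n_frames=1000, n_blocks=8
    )


class TestCorrelationProfile:
    def test_rigid_ensemble_has_unit_correlation_zero_sem(self):
        t = np.tile([0.0, 0.0, 1.0], (16, 5, 1))
        prof = cf.correlation_profile(_axis_from_tangents(t), n_blocks=4)
        np.testing.assert_allclose(prof.c, 1.0, atol=1e-12)
        np.testing.assert_allclose(prof.sem, 0.0, atol=1e-12)

    def test_two_frames_symmetric_about_z_give_cos_theta(self):
        theta = 0.4
        t = np.zeros((2, 3, 3))
        t[:, :, 2] = math.cos(theta)
        t[0, :, 0] = math.sin(theta)
        t[1, :, 0] = -math.sin(theta)
        prof = cf.correlation_profile(_axis_from_tangents(t), n_blocks=2)
        np.testing.assert_allclose(prof.c, math.cos(theta), atol=1e-12)

    def test_matches_double_loop_brute_force(self, rng):
        t = rng.normal(size=(12, 6, 3))
        t /= np.linalg.norm(t, axis=-1, keepdims=True)
        t[:, :, 2] += 2.0  # bias so the mean tangent cannot vanish
        t /= np.linalg.norm(t, axis=-1, keepdims=True)
        prof = cf.correlation_profile(_axis_from_tangents(t), n_blocks=1)
        for i in range(t.shape[1]):
            mean = np.zeros(3)
            for f in range(t.shape[0]):
                mean += t[f, i]
            mean /= np.linalg.norm(mean)
            want = sum(float(t[f, i] @ mean) for f in range(t.shape[0])) / t.shape[0]
            assert prof.c[i] == pytest.approx(want, abs=1e-12)

    def test_vanishing_mean_tangent_is_an_error(self):
        t = np.zeros((2, 3, 3))
        t[0, :, 2] = 1.0
        t[1, :, 2] = -1.0  # mean exactly zero everywhere
        with pytest.raises(ValueError, match="disordered"):
            cf.correlation_profile(_axis_from_tangents(t), n_blocks=1)

    def test_invariant_under_global_rotation(self, rng):
        wlc = cf.sample_wlc_ensemble(cf.WLCParams(lp_nm=60, n_frames=200, seed=4))
        base = cf.correlation_profile(wlc.to_axis_polyline())
        R = random_rotation(rng)
        rotated = cf.WLCEnsemble(
            vertices=wlc.vertices @ R.T, tangents=wlc.tangents @ R.T,
            params=wlc.params,
        )
        got = cf.correlation_profile(rotated.to_axis_polyline())
        np.testing.assert_allclose(got.c, base.c, atol=1e-9)
        np.testing.assert_allclose(got.s, base.s, atol=1e-9)


class TestFits:
    def test_exact_exponential_recovers_lp_with_zero_se(self):
        prof = _exact_profile(np.arange(10) * 1.5, 100.0)
        est = cf.fit_lp_least_squares(prof, 300.0)
        assert est.lp_nm == pytest.approx(100.0, rel=1e-9)
        assert est.lp_se_nm == pytest.approx(0.0, abs=1e-6)
        sec = cf.fit_lp_secant(prof, 300.0)
        assert sec.lp_nm == pytest.approx(100.0, rel=1e-9)

    def test_rigid_profile_reports_infinite_lp(self):
        prof = cf.CorrelationProfile(
            s=np.arange(5.0), c=np.ones(5), sem=np.zeros(5), n_frames=10, n_blocks=2
        )
        assert math.isinf(cf.fit_lp_least_squares(prof).lp_nm)
        assert math.isinf(cf.fit_lp_secant(prof).lp_nm)

    def test_nonpositive_correlation_is_an_error(self):
        prof = cf.CorrelationProfile(
            s=np.arange(4.0), c=np.array([1.0, 0.5, -0.1, 0.2]),
            sem=np.zeros(4), n_frames=10, n_blocks=2,
        )
        with pytest.raises(ValueError, match="non-positive"):
            cf.fit_lp_least_squares(prof)

    def test_secant_ignores_interior_sag_direct_arithmetic(self):
        # drop concentrated mid-chain: c sags below the endpoint exponential
        s = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.0, -0.05, -0.5, -0.55])
        prof = cf.CorrelationProfile(
            s=s, c=np.exp(y), sem=np.zeros(4), n_frames=10, n_blocks=2
        )
        sec = cf.fit_lp_secant(prof)
        lsq = cf.fit_lp_least_squares(prof)
        # oracle: secant slope from the endpoints alone
        assert sec.lp_nm == pytest.approx(-1.0 / ((y[3] - y[0]) / 3.0), rel=1e-12)
        # oracle: least-squares slope by direct arithmetic
        xc = s - s.mean()
        slope = float(xc @ y) / float(xc @ xc)
        assert lsq.lp_nm == pytest.approx(-1.0 / slope, rel=1e-12)
        assert sec.lp_nm > lsq.lp_nm

    def test_free_and_zero_intercept_agree_on_exact_line(self):
        prof = _exact_profile(np.arange(8) * 1.5, 42.0)
        free = cf.fit_lp_least_squares(prof)
        forced = cf.fit_lp_least_squares(prof, force_zero_intercept=True)
        assert free.lp_nm == pytest.approx(forced.lp_nm, rel=1e-9)

    def test_recovers_generator_truth_on_synthetic_chain(self):
        wlc = cf.sample_wlc_ensemble(
            cf.WLCParams(lp_nm=100.0, segment_length_nm=1.5, n_vertices=11,
                         n_frames=8000, seed=12)
        )
        prof = cf.correlation_profile(wlc.to_axis_polyline())
        est = cf.fit_lp_least_squares(prof, 300.0)
        assert est.lp_nm == pytest.approx(100.0, rel=0.10)


class TestStiffness:
    def test_closed_form_value(self):
        k = cf.stiffness_from_lp(100.0, 300.0)
        assert k == pytest.approx(100.0 * 1.380649e-23 * 300.0, rel=1e-12)

    def test_linearity_in_temperature(self):
        assert cf.stiffness_from_lp(50.0, 600.0) == pytest.approx(
            2 * cf.stiffness_from_lp(50.0, 300.0), rel=1e-12
        )

    def test_round_trip_inverse(self):
        for lp in (0.3, 98.4, 1e4):
            back = cf.lp_from_stiffness(cf.stiffness_from_lp(lp, 313.0), 313.0)
            assert back == pytest.approx(lp, rel=1e-12)


class TestFlexibility:
    def test_uniform_exponential_has_constant_local_slope(self):
        prof = _exact_profile(np.arange(10) * 1.5, 80.0)
        flex = cf.flexibility_profile(prof)
        np.testing.assert_allclose(flex.local_slope, -1.0 / 80.0, atol=1e-12)

    def test_soft_joint_is_localized_to_its_residue_interval(self):
        scheme = cf.SegmentScheme()
        wlc = cf.sample_wlc_ensemble(
            cf.WLCParams(lp_nm=100.0, n_frames=8000, seed=3, soft_joint=(5, 5.0))
        )
        prof = cf.correlation_profile(wlc.to_axis_polyline(scheme))
        flex = cf.flexibility_profile(prof, scheme)
        assert flex.most_flexible_index in (4, 5)
        lo, hi = flex.most_flexible_region()
        # joint 5 sits at vertex 5 = centre of segment 5 = residue 161
        assert lo <= 161 <= hi

    def test_region_label_format(self):
        prof = _exact_profile(np.arange(10) * 1.5, 80.0)
        flex = cf.flexibility_profile(prof, cf.SegmentScheme())
        label = flex.most_flexible_label()
        assert label.startswith("residues ")
        lo, hi = flex.most_flexible_region()
        assert 106 <= lo < hi <= 216


class TestCompare:
    def _est(self, lp):
        return cf.PersistenceEstimate(lp, 1.0, "least_squares", 300.0,
                                      cf.stiffness_from_lp(lp, 300.0))

    def test_identical_blocks_give_ratio_one_p_one(self):
        blocks = [100.0, 101.0, 99.0, 100.0]
        ratio, p = cf.compare_lp(self._est(100.0), self._est(100.0), blocks, blocks)
        assert ratio == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_separated_blocks_significant_by_hand_computed_t(self):
        a = [100.0, 101.0, 99.0, 100.0]
        b = [150.0, 151.0, 149.0, 150.0]
        ratio, p = cf.compare_lp(self._est(100.0), self._est(150.0), a, b)
        assert ratio == pytest.approx(100.0 / 150.0)
        # direct two-sample equal-variance t statistic
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
        tstat = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))
        from scipy import stats

        want = 2 * stats.t.sf(abs(tstat), na + nb - 2)
        assert p == pytest.approx(want, rel=1e-9)
        assert p < 0.01

    def test_too_few_blocks_raise(self):
        with pytest.raises(ValueError, match="2 block"):
            cf.compare_lp(self._est(1.0), self._est(1.0), [1.0], [1.0, 2.0])


class TestEstimatorFamilies:
    def test_straight_chain_mean_and_first_reference_agree(self):
        wlc = cf.sample_wlc_ensemble(cf.WLCParams(lp_nm=100, n_frames=8000, seed=21))
        axis = wlc.to_axis_polyline()
        lp_mean = cf.fit_lp_least_squares(cf.correlation_profile(axis)).lp_nm
        lp_first = cf.fit_lp_least_squares(
            cf.correlation_profile(axis, reference="first")
        ).lp_nm
        assert lp_first == pytest.approx(lp_mean, rel=0.05)

    def test_curved_chain_mean_reference_unbiased_first_reference_low(self):
        wlc = cf.sample_wlc_ensemble(
            cf.WLCParams(lp_nm=100, intrinsic_bend_deg=5.0, n_frames=8000, seed=22)
        )
        axis = wlc.to_axis_polyline()
        lp_mean = cf.fit_lp_least_squares(cf.correlation_profile(axis)).lp_nm
        lp_first = cf.fit_lp_least_squares(
            cf.correlation_profile(axis, reference="first")
        ).lp_nm
        assert lp_mean == pytest.approx(100.0, rel=0.15)
        assert lp_first < 0.7 * 100.0  # strongly biased toward flexibility

    def test_lp_invariant_to_uniform_time_rescaling(self):
        wlc = cf.sample_wlc_ensemble(cf.WLCParams(lp_nm=50, n_frames=400, seed=8))
        axis = wlc.to_axis_polyline()
        lp = cf.fit_lp_least_squares(cf.correlation_profile(axis)).lp_nm
        # frame order/time never enters except through blocking
        lp_again = cf.fit_lp_least_squares(cf.correlation_profile(axis, n_blocks=4)).lp_nm
        assert lp_again == pytest.approx(lp, rel=1e-12)
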