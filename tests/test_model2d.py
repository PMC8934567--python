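"""Two-dimensional voxel model: forward predictions, loss, filtering, fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from sfmap import model2d, synth
from sfmap.model2d import (
    Model2DParams,
    SubmodelMask,
    build_design,
    filter_voxels,
    fit,
    fit_many,
    gain,
    predict_response,
    preferred_period,
    voxel_loss,
)
from sfmap.stimulus import GridSpec


class TestPreferredPeriod:
    def test_affine_baseline(self):
        p = Model2DParams(sigma=2.2, a=0.12, b=0.35)
        assert preferred_period(p, 10.0, 0.0, 0.0) == pytest.approx(1.55)

    def test_relative_annulus_modulation(self):
        p = Model2DParams(sigma=2.2, a=0.12, b=0.35, p3=0.1)
        for thetav in (0.0, 1.0, 4.0):
            # annulus presents theta_l = theta_v at the pRF
            assert preferred_period(p, 5.0, thetav, thetav) == pytest.approx(0.95 * 1.1)

    def test_positive_p1_favors_vertical(self):
        p = Model2DParams(sigma=2.2, a=0.12, b=0.35, p1=0.06)
        rng = np.random.default_rng(0)
        for rv, tv in zip(rng.uniform(1, 12, 5), rng.uniform(0, 2 * math.pi, 5)):
            assert preferred_period(p, rv, tv, 0.0) > preferred_period(p, rv, tv, math.pi / 2)

    def test_nonpositive_period_rejected(self):
        p = Model2DParams(sigma=2.0, a=0.0, b=1.0, p1=-0.6, p2=-0.5)
        with pytest.raises(ValueError):
            preferred_period(p, 5.0, 0.0, 0.0)


class TestGain:
    def test_unit_gain_without_modulation(self):
        p = Model2DParams()
        assert gain(p, 1.2, 0.7) == 1.0

    def test_vertical_over_horizontal_ratio(self):
        # positive A1: vertical (theta_l = 0) gain 1.04, horizontal 0.96,
        # horizontal/vertical ~ 0.923 — an ~8% weaker horizontal response
        p = Model2DParams(A1=0.04)
        v = gain(p, 0.0, 0.0)
        h = gain(p, 0.0, math.pi / 2)
        assert v == pytest.approx(1.04)
        assert h == pytest.approx(0.96)
        assert h / v == pytest.approx(0.923, abs=1e-3)

    def test_absolute_gain_independent_of_retinotopic_angle(self):
        p = Model2DParams(A1=0.05, A2=-0.02)
        vals = [gain(p, tv, 0.3) for tv in np.linspace(0, 2 * math.pi, 9)]
        assert np.allclose(vals, vals[0])


class TestPredictResponse:
    def test_peak_at_preferred_frequency(self):
        p = Model2DParams(sigma=1.0, a=0.1, b=0.5)
        d = build_design(np.array([5.0]), np.array([0.5]))
        pv = preferred_period(p, 5.0, 0.5, d.theta_l[0])
        pred = predict_response(p, d)
        av = gain(p, 0.5, d.theta_l[0])
        # at w_l = 1/pv the prediction equals the gain; one octave away it
        # drops by exp(-1/2) for sigma = 1
        u = np.log2(d.omega_l[0] * pv)
        np.testing.assert_allclose(pred[0], av * np.exp(-u ** 2 / 2))

    def test_orientation_periodicity(self):
        p = synth.TEMPLATE_MODEL9
        d = build_design(np.array([3.0, 7.0]), np.array([0.2, 4.0]))
        d_shift = model2d.VoxelDesign(
            d.ecc, d.angle, d.omega_l, np.mod(d.theta_l + math.pi, math.pi)
        )
        np.testing.assert_allclose(
            predict_response(p, d), predict_response(p, d_shift)
        )


class TestVoxelLoss:
    def test_zero_at_proportionality(self):
        rng = np.random.default_rng(1)
        beta = rng.uniform(0.1, 1, 48)
        assert voxel_loss(beta, 3.7 * beta, 1.0) == pytest.approx(0.0, abs=1e-30)

    def test_hand_computed_value(self):
        assert voxel_loss([1.0, 0.0], [0.0, 1.0], 1.0) == pytest.approx(1.0)

    def test_precision_scaling(self):
        beta = np.array([1.0, 0.2, 0.5])
        pred = np.array([0.8, 0.3, 0.4])
        assert voxel_loss(beta, pred, 2.0) == pytest.approx(
            voxel_loss(beta, pred, 1.0) / 2
        )

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        beta=arrays(float, 8, elements=st.floats(0.05, 2.0)),
        scale=st.floats(0.1, 50.0),
    )
    def test_amplitude_scale_invariance(self, beta, scale):
        pred = np.roll(beta, 1)
        assert voxel_loss(scale * beta, pred, 1.0) == pytest.approx(
            voxel_loss(beta, pred, 1.0), rel=1e-9
        )

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            voxel_loss(np.zeros(4), np.ones(4), 1.0)


class TestFilterVoxels:
    def test_exclusion_rules(self):
        grid = GridSpec()
        ecc = np.array([13.0, 11.8, 5.0, 5.0, 1.0])
        size = np.array([0.5, 0.5, 0.5, 0.5, 0.5])
        betas = np.ones((5, 4))
        betas[3] = -0.1  # mean-negative voxel
        keep = filter_voxels(ecc, size, betas, grid)
        # outside stimulus; within one sd of the border; kept; negative; near fovea
        assert list(keep) == [False, False, True, False, False]


class TestFit:
    def test_noiseless_recovery_within_tolerance(self, noiseless_subject):
        mask9 = SubmodelMask(True, True, True, True, True, False)
        res = fit(
            noiseless_subject.design(), noiseless_subject.betas,
            noiseless_subject.sigma_v2, mask=mask9,
        )
        truth = noiseless_subject.ground_truth.to_array()
        got = res.params.to_array()
        nz = truth != 0
        assert np.all(np.abs(got[nz] - truth[nz]) / np.abs(truth[nz]) < 1e-3)
        assert res.converged

    def test_degenerate_submodel_constant_period(self):
        gt = Model2DParams(sigma=2.0, a=0.0, b=0.9)
        subj = synth.simulate_subject("s", gt, n_voxels=200, noise_scale=0.0, seed=2)
        res = fit(subj.design(), subj.betas, subj.sigma_v2,
                  mask=SubmodelMask(free_a=False, free_b=True))
        assert res.params.a == 0.0
        assert res.params.b == pytest.approx(0.9, rel=1e-3)

    def test_voxel_order_invariance(self, noiseless_subject):
        subj = noiseless_subject
        perm = np.random.default_rng(3).permutation(subj.n_voxels)
        mask = SubmodelMask(True, True)
        r1 = fit(subj.design(), subj.betas, subj.sigma_v2, mask=mask)
        sub2 = subj.subset(perm)
        r2 = fit(sub2.design(), sub2.betas, sub2.sigma_v2, mask=mask)
        np.testing.assert_allclose(
            r1.params.to_array(), r2.params.to_array(), atol=1e-6
        )

    def test_nesting_model9_reduces_to_model3(self, noiseless_subject):
        # with the orientation modulations at 0, the 9-parameter model's
        # predictions are bit-for-bit those of the affine-period model
        d = noiseless_subject.design()
        p3 = Model2DParams(sigma=2.1, a=0.11, b=0.4)
        mask9 = SubmodelMask(True, True, True, True, True, False)
        p9 = mask9.apply(p3)
        np.testing.assert_array_equal(
            predict_response(p3, d), predict_response(p9, d)
        )

    def test_min_voxel_requirement(self):
        subj = synth.simulate_subject("s", synth.TEMPLATE_MODEL9, n_voxels=10,
                                      noise_scale=0.0, seed=1)
        with pytest.raises(ValueError, match="50"):
            fit(subj.design(), subj.betas, subj.sigma_v2)

    def test_batched_fit_matches_individual(self):
        subs = [
            synth.simulate_subject(f"s{k}", synth.TEMPLATE_MODEL9, n_voxels=150 + 30 * k,
                                   noise_scale=0.2, seed=k)
            for k in range(2)
        ]
        mask = SubmodelMask(True, True)
        batch = fit_many([s.design() for s in subs], [s.betas for s in subs],
                         [s.sigma_v2 for s in subs], mask=mask, max_iter=2000)
        for s, br in zip(subs, batch):
            solo = fit(s.design(), s.betas, s.sigma_v2, mask=mask, max_iter=2000)
            np.testing.assert_allclose(
                solo.params.to_array(), br.params.to_array(), atol=2e-4
            )


class TestParameterRecoveryNoisy:
    def test_full_model_recovery_at_realistic_noise(self):
        subj = synth.simulate_subject(
            "s", synth.TEMPLATE_MODEL9, n_voxels=2000, noise_scale=0.3, seed=31
        )
        keep = filter_voxels(subj.ecc, subj.prf_size, subj.betas)
        sub = subj.subset(keep)
        mask9 = SubmodelMask(True, True, True, True, True, False)
        res = fit(sub.design(), sub.betas, sub.sigma_v2, mask=mask9)
        t = synth.TEMPLATE_MODEL9
        assert res.params.a == pytest.approx(t.a, rel=0.05)
        assert res.params.b == pytest.approx(t.b, rel=0.05)
        assert res.params.sigma == pytest.approx(t.sigma, rel=0.10)
        for name in ("p1", "p2", "p3", "p4"):
            assert getattr(res.params, name) == pytest.approx(
                getattr(t, name), abs=0.02
            )

    def test_pooled_responses_collapse_onto_log_gaussian(self, eligible_noisy):
        # histogram-alignment analog: responses plotted against w_l * p_v
        # collapse onto one log-Gaussian of width sigma
        subj = eligible_noisy
        gt = subj.ground_truth
        d = subj.design()
        pv = preferred_period(gt, d.ecc[:, None], d.angle[:, None], d.theta_l)
        av = gain(gt, d.angle[:, None], d.theta_l)
        x = np.log2(d.omega_l * pv).ravel()
        y = (subj.betas / av).ravel()
        bins = np.linspace(-2.5, 2.5, 11)
        centers = 0.5 * (bins[:-1] + bins[1:])
        prof = np.array([
            y[(x >= lo) & (x < hi)].mean() for lo, hi in zip(bins[:-1], bins[1:])
        ])
        expected = np.exp(-centers ** 2 / (2 * gt.sigma ** 2))
        assert np.all(np.abs(prof - expected) < 0.05)
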