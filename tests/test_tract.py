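import numpy as np
import pytest

import dbsdiff as dd
from dbsdiff.tract import (
    BallStickOptions,
    FiberModel,
    TrackingParams,
    angle_between_deg,
    fit_ball_and_stick,
    mean_orientation,
    track,
)

from .conftest import single_tensor_volume  # noqa: F401  (fixture helpers)


def straight_bundle_model(length=20, width=8):
    shape = (length, width, width)
    ori = np.zeros(shape + (2, 3))
    fr = np.zeros(shape + (2,))
    core = np.s_[:, width // 2 - 1: width // 2 + 1, width // 2 - 1: width // 2 + 1]
    bundle = np.zeros(shape, bool)
    bundle[core] = True
    ori[bundle, 0] = (1.0, 0.0, 0.0)
    fr[bundle, 0] = 1.0
    model = FiberModel.from_orientation_field(ori, fr, (2, 2, 2))
    seed = np.zeros(shape, bool)
    seed[1][bundle[1]] = True
    target = np.zeros(shape, bool)
    target[length - 3][bundle[length - 3]] = True
    return model, seed, target


class TestTrackingOracles:
    def test_straight_bundle_full_success(self):
        model, seed, target = straight_bundle_model()
        params = TrackingParams(samples=100, max_steps=500)
        res = track(model, seed, target, params=params, seed=0)
        assert np.all(res.seed_counts == 100)
        assert dd.connection_probability_index(res) == 100.0
        assert dd.streamline_density(res) == 100.0

    def test_right_angle_turn_terminates_all(self):
        shape = (20, 20, 6)
        ori = np.zeros(shape + (2, 3))
        fr = np.zeros(shape + (2,))
        leg1 = np.zeros(shape, bool); leg1[2:10, 9:11, 2:4] = True
        leg2 = np.zeros(shape, bool); leg2[9:11, 11:18, 2:4] = True
        ori[leg1, 0] = (1, 0, 0); fr[leg1, 0] = 1.0
        ori[leg2 & ~leg1, 0] = (0, 1, 0); fr[leg2 & ~leg1, 0] = 1.0
        model = FiberModel.from_orientation_field(ori, fr, (2, 2, 2))
        seed = np.zeros(shape, bool); seed[2][leg1[2]] = True
        target = np.zeros(shape, bool); target[9:11, 16:18, 2:4] = True
        res = track(model, seed, target,
                    params=TrackingParams(samples=50, curvature=0.2), seed=0)
        assert res.seed_counts.sum() == 0

    def test_unreachable_target_counts_zero(self):
        model, seed, _ = straight_bundle_model()
        target = np.zeros(model.shape, bool)
        target[0, 0, 0] = True  # off-bundle, never reached
        res = track(model, seed, target,
                    params=TrackingParams(samples=20, max_steps=200), seed=0)
        assert res.seed_counts.sum() == 0

    def test_empty_seed_raises(self):
        model, _, target = straight_bundle_model()
        with pytest.raises(ValueError, match="empty"):
            track(model, np.zeros(model.shape, bool), target)

    def test_overlapping_seed_target_raises(self):
        model, seed, _ = straight_bundle_model()
        with pytest.raises(ValueError, match="disjoint"):
            track(model, seed, seed.copy())

    def test_visitation_of_successes_spans_at_least_two_voxels(self):
        model, seed, target = straight_bundle_model()
        res = track(model, seed, target,
                    params=TrackingParams(samples=50, max_steps=500), seed=1)
        n_success = int(res.seed_counts.sum())
        assert n_success > 0
        assert res.visitation.sum() >= 2 * n_success
        assert np.all(res.visitation[res.seed_mask] > 0)

    def test_determinism_same_seed(self):
        model, seed, target = straight_bundle_model()
        params = TrackingParams(samples=60, max_steps=300)
        a = track(model, seed, target, params=params, seed=9)
        b = track(model, seed, target, params=params, seed=9)
        assert np.array_equal(a.success_counts, b.success_counts)
        assert np.array_equal(a.visitation, b.visitation)


def noisy_direction_model(sample_dirs, length=12, k=100):
    """Posterior with K samples per voxel mixing an x-aligned majority with
    the given off-axis (direction, fraction) components."""
    shape = (length, 6, 6)
    bundle = np.zeros(shape, bool)
    bundle[:, 2:4, 2:4] = True
    vox = np.argwhere(bundle)
    ori = np.zeros((len(vox), k, 2, 3), dtype=np.float32)
    ori[:, :, 0] = (1, 0, 0)
    start = 0
    for direction, frac in sample_dirs:
        n = int(round(frac * k))
        d = np.asarray(direction, dtype=np.float32)
        ori[:, start:start + n, 0] = d / np.linalg.norm(d)
        start += n
    fr = np.zeros((len(vox), k, 2), dtype=np.float32)
    fr[:, :, 0] = 1.0
    model = FiberModel(
        shape=shape, voxel_size=(2.0, 2.0, 2.0), voxel_indices=vox,
        orientations=ori, fractions=fr,
        diffusivity=np.full((len(vox), k), 1.2e-3, dtype=np.float32),
        support=np.ones(len(vox), dtype=np.int8),
    )
    return model, bundle


class TestStochasticTracking:
    def test_success_counts_vary_binomially(self):
        """Across independent RNG seeds, per-seed success counts have a
        variance consistent with a binomial law at the pooled rate."""
        model, bundle = noisy_direction_model([((0, 1, 0), 0.02)])
        seed = np.zeros(model.shape, bool); seed[1][bundle[1]] = True
        target = np.zeros(model.shape, bool); target[9][bundle[9]] = True
        params = TrackingParams(samples=150, max_steps=200)
        counts = np.array([
            track(model, seed, target, params=params, seed=s).seed_counts
            for s in range(15)
        ])  # (runs, seeds)
        p_hat = counts.mean() / params.samples
        assert 0.05 < p_hat < 0.95
        expected_var = params.samples * p_hat * (1 - p_hat)
        observed_var = counts.var(axis=0, ddof=1).mean()
        assert expected_var / 3 < observed_var < expected_var * 3

    def test_stricter_curvature_never_increases_success(self):
        """On a fixed model and RNG stream, raising the curvature threshold
        (stricter) can only terminate streamlines earlier."""
        model, bundle = noisy_direction_model(
            [((1, 1, 0), 0.15), ((0, 1, 0), 0.05)]
        )
        seed = np.zeros(model.shape, bool); seed[1][bundle[1]] = True
        target = np.zeros(model.shape, bool); target[9][bundle[9]] = True
        succ = []
        for curv in (0.0, 0.2, 0.5, 0.9):
            params = TrackingParams(samples=200, curvature=curv, max_steps=200)
            succ.append(int(track(model, seed, target, params=params,
                                  seed=3).seed_counts.sum()))
        assert all(a >= b for a, b in zip(succ, succ[1:]))
        # the 45° component survives curvature 0.5 but not 0.9
        assert succ[2] > succ[3]


class TestHelpers:
    def test_mean_orientation_handles_sign_flips(self):
        v = np.array([0.6, 0.8, 0.0])
        samples = np.array([v, -v, v, -v, v])
        m = mean_orientation(samples)
        assert angle_between_deg(m, v) < 1e-6

    def test_angle_between_is_axial(self):
        assert angle_between_deg((1, 0, 0), (-1, 0, 0)) == pytest.approx(0.0)
        assert angle_between_deg((1, 0, 0), (0, 1, 0)) == pytest.approx(90.0)


class TestBallStickFit:
    def test_single_stick_recovery_noiseless(self, scheme32):
        b, g = scheme32.bvals, scheme32.bvecs
        v1 = np.array([1.0, 0, 0])
        f, d, s0 = 0.7, 1.2e-3, 1000.0
        att = (1 - f) * np.exp(-b * d) + f * np.exp(-b * d * (g @ v1) ** 2)
        signal = (s0 * att).reshape(1, 1, 1, -1)
        vol = dd.DWIVolume(signal, scheme32, (2, 2, 2),
                           masks={"brain": np.ones((1, 1, 1), bool)})
        model = fit_ball_and_stick(
            vol, options=BallStickOptions(burn_in=600, n_samples=100), seed=5
        )
        assert model.support[0] == 1
        m = mean_orientation(model.orientations[0, :, 0])
        assert angle_between_deg(m, v1) < 5.0
        assert abs(model.fractions[0, :, 0].mean() - f) < 0.05
        assert model.diffusivity[0].mean() == pytest.approx(d, rel=0.1)

    def test_fit_mask_shape_checked(self, scheme32):
        vol = single_tensor_volume(scheme32, [1e-3] * 3, shape=(2, 2, 2))
        with pytest.raises(ValueError, match="mask shape"):
            fit_ball_and_stick(vol, mask=np.ones((3, 3, 3), bool))
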