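import numpy as np
import pytest

import dbsdiff as dd
from dbsdiff.phantom import (
    AIR, GM, Bundle, PhantomSpec, ball_mask, make_phantom,
    noiseless_signal, simulate_dwi,
)
from dbsdiff.rigid import RigidTransform, random_rigid_transforms


def straight_spec(**kw):
    defaults = dict(
        shape=(20, 20, 20),
        bundles=[Bundle(waypoints=[(3, 10, 10), (16, 10, 10)], radius=1.0, f=0.7)],
    )
    defaults.update(kw)
    return PhantomSpec(**defaults)


class TestMakePhantom:
    def test_straight_bundle_orientation(self):
        ph = make_phantom(straight_spec())
        vox = ph.n_fibers > 0
        assert vox.sum() > 0
        assert np.allclose(np.abs(ph.orientations[vox, 0, 0]), 1.0)
        assert np.allclose(ph.orientations[vox, 0, 1:], 0.0)

    def test_crossing_bundles_carry_two_orientations(self):
        spec = straight_spec(
            bundles=[
                Bundle(waypoints=[(3, 10, 10), (16, 10, 10)], radius=1.0, f=0.4),
                Bundle(waypoints=[(10, 3, 10), (10, 16, 10)], radius=1.0, f=0.4),
            ]
        )
        ph = make_phantom(spec)
        cross = ph.n_fibers == 2
        assert cross.any()
        assert np.allclose(np.abs(ph.orientations[cross, 0, 0]), 1.0)
        assert np.allclose(np.abs(ph.orientations[cross, 1, 1]), 1.0)

    def test_quarter_circle_tangent_accuracy(self):
        # quarter circle of radius 8 centred at (10, 10): param (10+8cos t, 10+8sin t)
        t = np.linspace(0, np.pi / 2, 40)
        wps = np.column_stack([10 + 8 * np.cos(t), 10 + 8 * np.sin(t), np.full_like(t, 10)])
        ph = make_phantom(straight_spec(shape=(22, 22, 22),
                                        bundles=[Bundle(wps, radius=1.0, f=0.7)]))
        vox = np.argwhere(ph.n_fibers > 0)
        for v in vox[::7]:
            # analytic tangent at nearest curve point: (−sin t, cos t, 0)
            dx, dy = v[0] - 10.0, v[1] - 10.0
            ang = np.arctan2(dy, dx)
            tangent = np.array([-np.sin(ang), np.cos(ang), 0.0])
            got = ph.orientations[tuple(v)][0]
            cos = abs(np.dot(got, tangent))
            assert np.degrees(np.arccos(np.clip(cos, 0, 1))) < 10.0

    def test_bundle_leaving_grid_raises(self):
        with pytest.raises(ValueError, match="leaves the grid"):
            make_phantom(
                straight_spec(bundles=[Bundle([(1, 10, 10), (25, 10, 10)], radius=1.0)])
            )

    def test_three_overlapping_bundles_raise(self):
        b = Bundle(waypoints=[(3, 10, 10), (16, 10, 10)], radius=1.0, f=0.3)
        with pytest.raises(ValueError, match="two bundles"):
            make_phantom(straight_spec(bundles=[b, b, b]))

    def test_shared_seed_target_label_raises(self):
        labels = np.zeros((20, 20, 20), dtype=int)
        labels[ball_mask((20, 20, 20), (4, 10, 10), 2)] = 1
        spec = straight_spec(
            roi_labels=labels,
            roi_defs={"a": 1},
            seed_rois=["a"],
            target_rois=["a"],
        )
        with pytest.raises(ValueError, match="share label"):
            make_phantom(spec)


class TestSimulate:
    def test_isotropic_closed_form(self, scheme32):
        # S = S0 exp(−b d): 1000 · exp(−0.8) ≈ 449.33 for d = 1.0e-3, b = 800
        spec = straight_spec(bundles=[], d_gm=1.0e-3, s0_gm=1.0)
        ph = make_phantom(spec)
        dwi = simulate_dwi(ph, scheme32, sigma=0.0)
        gm = ph.tissue == GM
        dwivols = dwi.signal[gm][:, scheme32.dwi_mask]
        assert np.allclose(dwivols, 1000.0 * np.exp(-0.8), rtol=1e-12)

    def test_perpendicular_stick_unattenuated(self):
        # stick f = 1 along x, gradient along y: (g·v)² = 0 ⇒ S = S0
        table = dd.GradientTable(
            np.array([0.0, 800.0]), np.array([[0, 0, 0], [0, 1, 0]])
        )
        spec = straight_spec(s0_wm=1.0)
        spec.bundles[0] = Bundle(spec.bundles[0].waypoints, radius=1.0, f=1.0)
        ph = make_phantom(spec)
        dwi = simulate_dwi(ph, table, sigma=0.0)
        fib = ph.n_fibers > 0
        assert np.allclose(dwi.signal[fib, 1], 1000.0, rtol=1e-12)

    def test_b0_equals_voxel_s0(self, scheme32):
        ph = make_phantom(straight_spec())
        dwi = simulate_dwi(ph, scheme32, sigma=0.0)
        b0 = dwi.signal[..., scheme32.b0_index]
        spec = ph.spec
        assert np.allclose(b0[ph.tissue == GM], spec.s0 * spec.s0_gm, rtol=1e-12)
        assert np.allclose(b0[ph.n_fibers > 0], spec.s0 * spec.s0_wm, rtol=1e-12)
        assert np.all(b0[ph.tissue == AIR] == 0.0)

    def test_fraction_sum_above_one_raises(self, scheme32):
        spec = straight_spec(
            bundles=[
                Bundle(waypoints=[(3, 10, 10), (16, 10, 10)], radius=1.0, f=0.7),
                Bundle(waypoints=[(10, 3, 10), (10, 16, 10)], radius=1.0, f=0.7),
            ]
        )
        ph = make_phantom(spec)
        with pytest.raises(ValueError, match="sum above 1"):
            simulate_dwi(ph, scheme32, sigma=0.0)

    def test_noiseless_matches_independent_closed_form(self, scheme32):
        """Oracle: re-evaluate the ball-and-stick equation voxel by voxel
        with plain Python loops and compare to the vectorized simulator."""
        ph = make_phantom(straight_spec())
        signal = noiseless_signal(ph, scheme32)
        spec = ph.spec
        rng = np.random.default_rng(0)
        fib = np.argwhere(ph.n_fibers > 0)
        for v in fib[rng.choice(len(fib), 5, replace=False)]:
            fr = ph.fractions[tuple(v)]
            ori = ph.orientations[tuple(v)]
            for n in range(len(scheme32)):
                b, g = scheme32.bvals[n], scheme32.bvecs[n]
                s = (1 - fr.sum()) * np.exp(-b * spec.d_wm)
                for i in range(2):
                    if fr[i] > 0:
                        s += fr[i] * np.exp(-b * spec.d_wm * np.dot(g, ori[i]) ** 2)
                expected = spec.s0 * spec.s0_wm * s
                assert abs(signal[tuple(v)][n] - expected) <= 1e-12 * expected

    def test_rician_background_mean(self, study_phantom, scheme32):
        """Air magnitude is Rayleigh: mean = sigma · sqrt(π/2) within 2%."""
        sigma = 30.0
        dwi = simulate_dwi(study_phantom, scheme32, sigma=sigma, seed=3)
        air = dwi.signal[dwi.mask("air")]
        assert air.size > 1e5
        assert abs(air.mean() - sigma * np.sqrt(np.pi / 2)) < 0.02 * air.mean()

    def test_determinism(self, study_phantom, scheme32):
        a = simulate_dwi(study_phantom, scheme32, sigma=10.0, seed=42)
        b = simulate_dwi(study_phantom, scheme32, sigma=10.0, seed=42)
        assert np.array_equal(a.signal, b.signal)
        c = simulate_dwi(study_phantom, scheme32, sigma=10.0, seed=43)
        assert not np.array_equal(a.signal, c.signal)

    def test_dropout_reduces_clean_signal_before_noise(self, study_phantom, scheme32):
        mask = study_phantom.artifact_mask
        dwi = simulate_dwi(study_phantom, scheme32, sigma=0.0,
                           dropout_mask=mask, dropout_attenuation=0.25)
        ref = simulate_dwi(study_phantom, scheme32, sigma=0.0)
        assert np.allclose(dwi.signal[mask], 0.25 * ref.signal[mask])
        assert np.array_equal(dwi.signal[~mask], ref.signal[~mask])


class TestArtifact:
    def test_attenuation_extremes(self, pre_dwi, study_phantom):
        mask = study_phantom.artifact_mask
        zero = dd.apply_artifact(pre_dwi, mask, 0.0)
        assert np.all(zero.signal[mask] == 0.0)
        ident = dd.apply_artifact(pre_dwi, mask, 1.0)
        assert np.array_equal(ident.signal, pre_dwi.signal)

    def test_scaling_and_outside_voxels(self, pre_dwi, study_phantom):
        mask = study_phantom.artifact_mask
        out = dd.apply_artifact(pre_dwi, mask, 0.1)
        assert np.allclose(out.signal[mask], 0.1 * pre_dwi.signal[mask])
        assert np.array_equal(out.signal[~mask], pre_dwi.signal[~mask])

    def test_invalid_attenuation(self, pre_dwi, study_phantom):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            dd.apply_artifact(pre_dwi, study_phantom.artifact_mask, 1.5)


class TestMotion:
    def test_identity_is_exact(self, pre_dwi):
        trs = [RigidTransform.identity() for _ in range(pre_dwi.n_volumes)]
        out = dd.apply_motion(pre_dwi, trs)
        assert np.allclose(out.signal, pre_dwi.signal, atol=1e-6)

    def test_integer_voxel_translation_is_exact_shift(self, pre_dwi):
        trs = [RigidTransform.identity() for _ in range(pre_dwi.n_volumes)]
        trs[3] = RigidTransform([2.0, 0, 0], [0, 0, 0])  # exactly 1 voxel at 2 mm
        out = dd.apply_motion(pre_dwi, trs)
        assert np.allclose(out.signal[1:, :, :, 3], pre_dwi.signal[:-1, :, :, 3],
                           atol=1e-9)

    def test_random_motion_reproducible(self, pre_dwi):
        def build(seed):
            rng = np.random.default_rng(seed)
            trs = random_rigid_transforms(pre_dwi.n_volumes, 1.0, 1.0, rng)
            trs[pre_dwi.b0_index] = RigidTransform.identity()
            return dd.apply_motion(pre_dwi, trs)

        assert np.array_equal(build(5).signal, build(5).signal)

    def test_b0_transform_must_be_identity(self, pre_dwi):
        trs = [RigidTransform.identity() for _ in range(pre_dwi.n_volumes)]
        trs[pre_dwi.b0_index] = RigidTransform([1, 0, 0], [0, 0, 0])
        with pytest.raises(ValueError, match="identity"):
            dd.apply_motion(pre_dwi, trs)

    def test_excessive_motion_raises(self, pre_dwi):
        trs = [RigidTransform.identity() for _ in range(pre_dwi.n_volumes)]
        trs[2] = RigidTransform([30.0, 0, 0], [0, 0, 0])
        with pytest.raises(ValueError, match="25%"):
            dd.apply_motion(pre_dwi, trs)
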