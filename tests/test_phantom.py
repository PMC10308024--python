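"""Phantom generator: geometry, noise isolation, scenes, cohorts, protocols."""

import numpy as np
import pytest

from hippofactory import phantom as ph
from hippofactory.loss import CANONICAL_LABELS, ProtocolSpec
from hippofactory.metrics import dice


class TestHippocampusPhantom:
    def test_noiseless_intensities_are_exact_class_means(self, noiseless_phantom):
        vol, lab = noiseless_phantom
        for name, mean in ph.DEFAULT_INTENSITIES.items():
            mask = lab.data == CANONICAL_LABELS[name]
            if mask.any():
                np.testing.assert_allclose(vol.data[mask], mean)

    def test_noise_isolation_across_seeds(self):
        base = dict(noise_sd=0.07)
        v1, l1 = ph.make_hippocampus_phantom(ph.PhantomSpec(seed=1, **base))
        v2, l2 = ph.make_hippocampus_phantom(ph.PhantomSpec(seed=2, **base))
        v0, _ = ph.make_hippocampus_phantom(
            ph.PhantomSpec(seed=1, noise_sd=0.0))
        np.testing.assert_array_equal(l1.data, l2.data)
        assert not np.array_equal(v1.data, v2.data)
        # the deviation from the noiseless image is pure seeded noise
        resid = v1.data - v0.data
        assert abs(resid.std() - 0.07) < 0.005
        assert abs(resid.mean()) < 0.005

    def test_head_tail_phantom_emits_seven_foreground_classes(self):
        _, lab = ph.make_hippocampus_phantom(ph.PhantomSpec(include_head_tail=True))
        ids, counts = np.unique(lab.data, return_counts=True)
        foreground = {int(i): int(c) for i, c in zip(ids, counts) if i != 0}
        assert set(foreground) == {1, 2, 3, 4, 5, 6, 7}
        assert all(c >= 1 for c in foreground.values())

    def test_determinism_bit_identical(self):
        spec = ph.PhantomSpec(seed=9)
        v1, l1 = ph.make_hippocampus_phantom(spec)
        v2, l2 = ph.make_hippocampus_phantom(ph.PhantomSpec(seed=9))
        np.testing.assert_array_equal(v1.data, v2.data)
        np.testing.assert_array_equal(l1.data, l2.data)

    def test_too_small_grid_names_missing_class(self):
        with pytest.raises(ValueError, match="too small to carve"):
            ph.make_hippocampus_phantom(
                ph.PhantomSpec(grid_shape=(16, 16, 16), radius_fraction=0.06))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ph.PhantomSpec(grid_shape=(8, 32, 32))
        with pytest.raises(ValueError):
            ph.PhantomSpec(noise_sd=-0.1)


class TestHeadScene:
    def test_identity_pose_crop_matches_phantom(self):
        spec = ph.PhantomSpec(grid_shape=(16, 16, 16))
        bundle = ph.make_head_scene(spec, scene_shape=(48, 48, 48))
        _, lab = ph.make_hippocampus_phantom(spec)
        crop = bundle.scene_labels.data[bundle.box_left.slices()]
        # canonical pose is an integer translation and the ground-truth box
        # is the foreground hull: exact label recovery on that hull
        fg = np.argwhere(lab.data > 0)
        lo, hi = fg.min(axis=0), fg.max(axis=0) + 1
        hull = lab.data[tuple(slice(a, b) for a, b in zip(lo, hi))]
        np.testing.assert_array_equal(crop, hull)

    def test_translation_shifts_ground_truth_box_exactly(self):
        spec = ph.PhantomSpec(grid_shape=(16, 16, 16))
        cl, cr = ph.canonical_poses(spec, (48, 48, 48))
        t = np.eye(4)
        t[:3, 3] = [5, 0, 0]
        b0 = ph.make_head_scene(spec, scene_shape=(48, 48, 48))
        b1 = ph.make_head_scene(spec, t @ cl, t @ cr, scene_shape=(48, 48, 48))
        np.testing.assert_array_equal(b1.box_left.lo, b0.box_left.lo + [5, 0, 0])
        np.testing.assert_array_equal(b1.box_left.hi, b0.box_left.hi + [5, 0, 0])

    def test_left_right_boxes_disjoint(self, small_scene):
        bl, br = small_scene.box_left, small_scene.box_right
        assert bl.hi[0] <= br.lo[0] or br.hi[0] <= bl.lo[0]

    def test_pose_outside_fov_errors(self):
        spec = ph.PhantomSpec(grid_shape=(16, 16, 16))
        cl, cr = ph.canonical_poses(spec, (48, 48, 48))
        t = np.eye(4)
        t[:3, 3] = [40, 0, 0]
        with pytest.raises(ValueError, match="field of view"):
            ph.make_head_scene(spec, t @ cl, t @ cr, scene_shape=(48, 48, 48))

    def test_scene_roundtrip_dice_under_fractional_pose(self):
        # worst-case half-voxel pose at the default phantom size:
        # resampling tolerance, Dice >= 0.95
        from scipy import ndimage
        spec = ph.PhantomSpec()
        sc = tuple(3 * s for s in spec.grid_shape)
        cl, cr = ph.canonical_poses(spec, sc)
        t = np.eye(4)
        t[:3, 3] = [0.5, 0.3, -0.4]
        bundle = ph.make_head_scene(spec, t @ cl, t @ cr, scene_shape=sc)
        _, lab = ph.make_hippocampus_phantom(spec)
        # pull the scene foreground back onto the phantom grid at the
        # recorded pose (anti-aliased indicator resampling)
        pose = bundle.pose_left
        fg = (bundle.scene_labels.data > 0).astype(float)
        recovered = ndimage.affine_transform(
            fg, pose[:3, :3], offset=pose[:3, 3],
            output_shape=lab.shape, order=1) > 0.5
        assert dice(recovered, lab.data > 0) >= 0.95


class TestLifespanCohort:
    def test_noiseless_points_lie_on_generating_curve(self):
        spec = ph.LifespanSpec(n_subjects=40, noise_sd=0.0, seed=3)
        df = ph.make_lifespan_cohort(spec)
        for region, per_sex in spec.region_params.items():
            for sex in ("F", "M"):
                sub = df[(df.region == region) & (df.sex == sex)]
                expected = ph.generating_curve(sub.age.to_numpy(),
                                               per_sex[sex], spec.knot_ages,
                                               spec.blend_years)
                np.testing.assert_allclose(sub.volume_mm3.to_numpy(), expected)

    def test_decay_after_knot_lowers_volumes(self):
        # decay onset at 70: mean volume over ages 80-90 < mean over 55-65
        spec = ph.LifespanSpec(n_subjects=1000, seed=5)
        df = ph.make_lifespan_cohort(spec)
        dg = df[df.region == "DG"]
        old = dg[(dg.age >= 80) & (dg.age <= 90)].volume_mm3.mean()
        plateau = dg[(dg.age >= 55) & (dg.age <= 65)].volume_mm3.mean()
        assert old < plateau

    def test_male_plateau_offset(self):
        spec = ph.LifespanSpec(n_subjects=1000, seed=6)
        df = ph.make_lifespan_cohort(spec)
        dg = df[(df.region == "DG") & (df.age >= 30) & (df.age <= 60)]
        assert dg[dg.sex == "M"].volume_mm3.mean() > \
            dg[dg.sex == "F"].volume_mm3.mean()

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            ph.LifespanSpec(noise_sd=-1.0)

    def test_determinism(self):
        a = ph.make_lifespan_cohort(ph.LifespanSpec(n_subjects=30, seed=11))
        b = ph.make_lifespan_cohort(ph.LifespanSpec(n_subjects=30, seed=11))
        assert a.equals(b)

    def test_generating_curve_is_continuous_with_linear_tails(self):
        params = (20.0, 1000.0, -15.0)
        ages = np.linspace(0, 110, 2000)
        y = ph.generating_curve(ages, params, (22.0, 70.0))
        # continuity: no jump larger than slope * step
        assert np.abs(np.diff(y)).max() < 25 * (ages[1] - ages[0])
        # linear tails: exact slopes outside the blend zones
        left = ages < 10
        slopes = np.diff(y[left]) / np.diff(ages[left])
        np.testing.assert_allclose(slopes, 20.0, rtol=1e-9)
        right = ages > 85
        slopes = np.diff(y[right]) / np.diff(ages[right])
        np.testing.assert_allclose(slopes, -15.0, rtol=1e-9)


class TestProtocolVariants:
    def test_identity_protocol_is_identity(self, default_phantom):
        _, lab = default_phantom
        out = ph.make_protocol_variants(lab, ProtocolSpec())
        np.testing.assert_array_equal(out.data, lab.data)

    def test_merge_histogram_additivity(self, default_phantom):
        _, lab = default_phantom
        proto = ProtocolSpec(merge_groups=[{"CA2", "CA3"}])
        out = ph.make_protocol_variants(lab, proto)
        ca2, ca3 = CANONICAL_LABELS["CA2"], CANONICAL_LABELS["CA3"]
        merged = int((out.data == ca2).sum())
        assert merged == int((lab.data == ca2).sum() + (lab.data == ca3).sum())
        assert not (out.data == ca3).any()

    def test_head_cap_removes_anterior_subfields(self):
        spec = ph.PhantomSpec(include_head_tail=False)
        _, lab = ph.make_hippocampus_phantom(spec)
        # geometric head mask: anterior 25% of the anteroposterior axis
        mask = np.zeros(lab.shape, dtype=bool)
        mask[:, :lab.shape[1] // 4, :] = True
        out = ph.make_protocol_variants(lab, ProtocolSpec(head=True),
                                        head_mask=mask)
        subfields = np.isin(out.data[mask], [1, 2, 3, 4, 5])
        assert not subfields.any()
        assert (out.data[mask] == CANONICAL_LABELS["HEAD"]).sum() == \
            (lab.data[mask] > 0).sum()

    def test_foreground_conservation(self, default_phantom):
        _, lab = default_phantom
        for proto in (ProtocolSpec(merge_groups=[{"CA1", "CA2", "CA3"}]),
                      ProtocolSpec(head=True, tail=True),
                      ProtocolSpec(merge_groups=[{"DG", "SUB"}], head=True)):
            out = ph.make_protocol_variants(lab, proto)
            assert int((out.data > 0).sum()) == int((lab.data > 0).sum())

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ProtocolSpec(merge_groups=[{"CA9"}])
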