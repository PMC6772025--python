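"""Radiality metrics: per-voxel definitions, profile and ROI aggregation."""

import numpy as np
import pytest

import cortrad as ct
from cortrad.metrics import DIFFUSIVITY_SCALE
from cortrad.volumes import matrices_to_tensors


class TestVoxelAngle:
    def test_aligned_perpendicular_antipodal(self):
        z = np.array([0.0, 0.0, 1.0])
        x = np.array([1.0, 0.0, 0.0])
        assert ct.voxel_angleR(z, z) == 0.0
        assert ct.voxel_angleR(x, z) == pytest.approx(np.pi / 2)
        assert ct.voxel_angleR(-z, z) == 0.0
        assert ct.voxel_angleR(z, -z) == 0.0

    def test_range_and_sign_invariance_on_random_pairs(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=(100, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        v = rng.normal(size=(100, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        ang = ct.voxel_angleR(u, v)
        assert ((ang >= 0) & (ang <= np.pi / 2 + 1e-12)).all()
        assert np.array_equal(ct.voxel_angleR(-u, v), ang)
        assert np.array_equal(ct.voxel_angleR(u, -v), ang)

    def test_non_unit_input_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            ct.voxel_angleR(np.array([0.0, 0.0, 2.0]), np.array([0.0, 0.0, 1.0]))


class TestProjections:
    def test_exact_trigonometry(self):
        z = np.array([0.0, 0.0, 1.0])
        x = np.array([1.0, 0.0, 0.0])
        assert ct.voxel_projections(1.0, z, z) == (pytest.approx(1.0), pytest.approx(0.0))
        assert ct.voxel_projections(1.0, x, z) == (pytest.approx(0.0), pytest.approx(1.0))
        e = np.array([np.sin(np.pi / 3), 0.0, np.cos(np.pi / 3)])
        parl, perp = ct.voxel_projections(0.8e-3, e, z)
        assert parl == pytest.approx(0.4e-3, rel=1e-12)
        assert perp == pytest.approx(0.8e-3 * np.sqrt(3) / 2, rel=1e-12)

    def test_pythagorean_identity_per_voxel(self):
        rng = np.random.default_rng(1)
        e = rng.normal(size=(200, 3))
        e /= np.linalg.norm(e, axis=1, keepdims=True)
        r = rng.normal(size=(200, 3))
        r /= np.linalg.norm(r, axis=1, keepdims=True)
        lam1 = rng.uniform(0.1e-3, 2e-3, size=200)
        parl, perp = ct.voxel_projections(lam1, e, r)
        assert np.abs(parl**2 + perp**2 - lam1**2).max() < 1e-10 * (2e-3) ** 2

    def test_negative_lambda1_rejected(self):
        z = np.array([0.0, 0.0, 1.0])
        with pytest.raises(ValueError, match="negative"):
            ct.voxel_projections(-1.0, z, z)


class TestProfileMean:
    def test_constant_field_gives_exact_constant(self, slab):
        cortex = slab["truth"].labels.cortex_mask
        vol = ct.ScalarVolume(np.where(cortex, 3.25, 0.0), np.eye(4), cortex)
        for prof in slab["profiles"][:10]:
            assert ct.profile_mean(vol, prof) == 3.25

    def test_depth_metric_averages_to_half(self, slab):
        truth = slab["truth"]
        cortex = truth.labels.cortex_mask
        depth = np.where(cortex, truth.depth_fraction, 0.0)
        vol = ct.ScalarVolume(depth, np.eye(4), cortex)
        means = [ct.profile_mean(vol, p) for p in slab["profiles"]]
        assert abs(np.mean(means) - 0.5) < 0.25 / 10.0 + 0.05

    def test_fully_flagged_profile_returns_nan(self, slab):
        cortex = slab["truth"].labels.cortex_mask
        vol = ct.ScalarVolume(np.zeros(cortex.shape), np.eye(4),
                              np.zeros(cortex.shape, bool))
        assert np.isnan(ct.profile_mean(vol, slab["profiles"][0]))

    def test_short_profile_rejected(self, slab):
        cortex = slab["truth"].labels.cortex_mask
        vol = ct.ScalarVolume(np.zeros(cortex.shape), np.eye(4), cortex)
        prof = slab["profiles"][0]
        short = ct.CorticalProfile(
            points=prof.points[:1], potentials=prof.potentials[:1],
            arc_length_mm=0.0, seed_voxel=prof.seed_voxel, step_mm=prof.step_mm,
        )
        with pytest.raises(ValueError, match="2 samples"):
            ct.profile_mean(vol, short)


def _slab_maps_and_profiles(slab):
    tensors = slab["tensors"]
    eig = ct.eigendecompose(tensors)
    maps = ct.compute_voxel_metrics(
        eig, slab["field"], ct.fa_map(eig), ct.md_map(eig)
    )
    return eig, maps


class TestRoiSummarize:
    def test_identical_values_pass_through(self, slab):
        _, maps = _slab_maps_and_profiles(slab)
        roi = ct.ROIDefinition(mask=slab["truth"].labels.cortex_mask,
                               region="whole", slice_axis=1)
        out = ct.roi_summarize(maps, slab["profiles"], roi)
        # zero-dispersion slab: AngleR identically 0, ParlPD = lambda1
        assert out.angleR == 0.0
        assert out.parlPD == pytest.approx(0.8e-3 * DIFFUSIVITY_SCALE, rel=1e-9)
        assert out.perpPD == pytest.approx(0.0, abs=1e-12)

    def test_terminal_slice_outliers_do_not_change_result(self, slab):
        eig, maps = _slab_maps_and_profiles(slab)
        cortex = slab["truth"].labels.cortex_mask
        roi = ct.ROIDefinition(mask=cortex, region="whole", slice_axis=1)
        lo, hi = roi.slice_range
        base = ct.roi_summarize(maps, slab["profiles"], roi)
        # poison the MD map in the terminal slices only
        md = maps["MD"].data.copy()
        md[:, lo, :] = 99.0
        md[:, hi, :] = 99.0
        maps2 = dict(maps)
        maps2["MD"] = ct.ScalarVolume(md, maps["MD"].affine, maps["MD"].mask)
        poisoned = ct.roi_summarize(maps2, slab["profiles"], roi)
        assert poisoned.md == base.md

    def test_empty_after_exclusion_raises_with_roi_name(self, slab):
        _, maps = _slab_maps_and_profiles(slab)
        cortex = slab["truth"].labels.cortex_mask
        mask = np.zeros_like(cortex)
        mask[:, 5, :] = cortex[:, 5, :]  # single slice: everything terminal
        roi = ct.ROIDefinition(mask=mask, region="single_slice", slice_axis=1)
        with pytest.raises(ValueError, match="single_slice"):
            ct.roi_summarize(maps, slab["profiles"], roi)


class TestEndToEnd:
    def test_zero_dispersion_slab_roi_angle_below_002(self, zero_dispersion_dwi_result):
        truth, result = zero_dispersion_dwi_result
        assert result.roi_metrics[0].angleR < 0.02

    def test_uniform_axes_roi_angle_is_one_radian(self, uniform_axes_result):
        truth, result = uniform_axes_result
        assert int(truth.labels.cortex_mask.sum()) >= 10_000
        assert abs(result.roi_metrics[0].angleR - 1.0) < 0.03

    def test_roi_angle_monotone_in_dispersion(self):
        angles = []
        for kappa in (np.inf, 16.0, 8.0, 4.0, 2.0, 0.0):
            spec = ct.PhantomSpec(grid_shape=(24, 24, 24), cortex_thickness=10.0,
                                  dispersion_kappa=kappa, seed=7)
            _, result = ct.process_phantom(spec, through_dwi=False)
            angles.append(result.roi_metrics[0].angleR)
        assert all(a <= b + 1e-12 for a, b in zip(angles, angles[1:]))

    def test_antipodal_invariance_is_bit_exact(self, slab):
        eig = ct.eigendecompose(slab["tensors"])
        field = slab["field"]
        fa, md = ct.fa_map(eig), ct.md_map(eig)
        roi = ct.ROIDefinition(mask=slab["truth"].labels.cortex_mask,
                               region="whole", slice_axis=1)

        maps = ct.compute_voxel_metrics(eig, field, fa, md)
        base = ct.roi_summarize(maps, slab["profiles"], roi)

        flipped_eig = ct.EigenVolume(
            eigenvalues=eig.eigenvalues, eigenvectors=-eig.eigenvectors,
            affine=eig.affine, mask=eig.mask, degenerate=eig.degenerate,
        )
        flipped_field = ct.RadialField(
            vectors=-field.vectors, affine=field.affine,
            mask=field.mask, flagged=field.flagged,
        )
        for e, f in [(flipped_eig, field), (eig, flipped_field),
                     (flipped_eig, flipped_field)]:
            # profiles are retraced only when the field flips orientation;
            # the voxel metrics themselves must be bit-identical
            maps2 = ct.compute_voxel_metrics(e, f, fa, md)
            for name in maps:
                assert np.array_equal(maps[name].data, maps2[name].data)
            out = ct.roi_summarize(maps2, slab["profiles"], roi)
            assert out == base

    def test_rotated_slab_gives_same_roi_angle(self):
        # rotate the whole phantom by 90 degrees (z -> x) and rerun; AngleR
        # may differ only through discretization
        spec = ct.PhantomSpec(grid_shape=(20, 20, 20), cortex_thickness=8.0,
                              dispersion_kappa=4.0, seed=13)
        truth, tensors = ct.make_phantom(spec)
        result = ct.analyze_subject(tensors, truth.labels)
        base = result.roi_metrics[0].angleR

        # rotate arrays about the y axis: new[i,j,k] = old[k, j, N-1-i],
        # i.e. (x, y, z) -> (-z, y, x) with linear part R
        def rot_array(a):
            return np.flip(np.transpose(a, (2, 1, 0) + tuple(range(3, a.ndim))),
                           axis=0).copy()

        R = np.array([[0.0, 0, -1], [0, 1, 0], [1, 0, 0]])
        labels_rot = ct.TissueLabelVolume(
            rot_array(truth.labels.labels),
            truth.labels.affine, truth.labels.voxel_size,
        )
        mats = tensors.as_matrices()
        mats_rot = np.einsum("ij,...jk,lk->...il", R, mats, R)
        comp_rot = rot_array(matrices_to_tensors(mats_rot))
        tensors_rot = ct.TensorVolume(comp_rot, tensors.affine, labels_rot.cortex_mask)
        result_rot = ct.analyze_subject(tensors_rot, labels_rot)
        assert abs(result_rot.roi_metrics[0].angleR - base) < 0.02
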