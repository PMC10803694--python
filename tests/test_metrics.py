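"""Jacobian stage chain, group maps, Jac-mean, template and Dice."""

import numpy as np
import pytest

from lungdeform import (
    AffineTransform,
    BinaryMask,
    DisplacementField,
    dice_to_template,
    group_average,
    healthy_template,
    jac_mean,
    jacobian_map,
    log_jac,
    marked_deformation_mask,
    normalize_jac,
    to_common_space,
    true_field,
    true_jacobian,
)
from lungdeform.grid import Geometry
from lungdeform.metrics import GroupAverageMap, axis_projection
from lungdeform.preprocess import lung_volume
from lungdeform.qc import iou


def linear_field(geom, A, center=None):
    """u(x) = (A - I)(x - c): Jacobian of id + u is det(A) everywhere."""
    xs, ys, zs = geom.world_coordinates()
    pts = np.stack([xs, ys, zs], axis=-1)
    c = np.asarray(center if center is not None else geom.extent_mm / 2)
    u = (pts - c) @ (np.asarray(A) - np.eye(3)).T
    return DisplacementField(u, geom)


def full_mask(geom):
    return BinaryMask(np.ones(geom.shape, dtype=np.uint8), geom)


def interior(geom, margin=2):
    m = np.zeros(geom.shape, dtype=np.uint8)
    m[margin:-margin, margin:-margin, margin:-margin] = 1
    return BinaryMask(m, geom)


GEOM = Geometry((24, 24, 24), (2.0, 2.0, 2.0))


class TestJacobianMap:
    def test_zero_field_gives_unity(self):
        fld = DisplacementField(np.zeros(GEOM.shape + (3,)), GEOM)
        jac = jacobian_map(fld, mask=full_mask(GEOM))
        np.testing.assert_allclose(jac.values, 1.0, atol=1e-12)
        assert jac.stage == "JAC"

    def test_uniform_scaling_is_s_cubed(self):
        s = 0.8
        jac = jacobian_map(linear_field(GEOM, np.diag([s, s, s])),
                           mask=interior(GEOM))
        inside = interior(GEOM).astype_bool()
        np.testing.assert_allclose(jac.values[inside], s**3, atol=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_general_linear_field_gives_det(self, seed):
        rng = np.random.default_rng(seed)
        A = np.eye(3) + 0.2 * rng.uniform(-1, 1, (3, 3))
        assert abs(np.linalg.det(A)) > 0.3  # well-conditioned draw
        jac = jacobian_map(linear_field(GEOM, A), mask=interior(GEOM))
        inside = interior(GEOM).astype_bool()
        np.testing.assert_allclose(jac.values[inside], np.linalg.det(A), atol=1e-6)

    def test_matches_finite_difference_oracle_on_phantom(self, phantom):
        fld = true_field(phantom.model, phantom.expiration.geometry)
        jac = jacobian_map(fld, mask=phantom.lung_mask_exp)
        geom = phantom.expiration.geometry
        xs, ys, zs = geom.world_coordinates()
        pts = np.stack([xs, ys, zs], axis=-1)
        lung = phantom.lung_mask_exp.astype_bool()
        oracle = true_jacobian(phantom.model, pts[lung])
        np.testing.assert_allclose(jac.values[lung], oracle, rtol=0.01)

    def test_conservation_of_lung_volume(self, phantom):
        # change of variables: lung-mean JAC ~ V_insp / V_exp
        fld = true_field(phantom.model, phantom.expiration.geometry)
        jac = jacobian_map(fld, mask=phantom.lung_mask_exp)
        ratio = lung_volume(phantom.lung_mask_insp) / lung_volume(phantom.lung_mask_exp)
        lung = phantom.lung_mask_exp.astype_bool()
        assert jac.values[lung].mean() == pytest.approx(ratio, rel=0.03)

    def test_clipping_reported(self):
        # a violently contracting linear map drives det below the clip floor
        jac = jacobian_map(linear_field(GEOM, np.diag([1e-4, 1e-4, 1e-4])),
                           mask=interior(GEOM))
        assert jac.provenance["clipped_voxels"] > 0
        assert np.all(jac.values >= 1e-6)


class TestNormalizeAndLog:
    def make_jac(self, value=2.0):
        fld = DisplacementField(np.zeros(GEOM.shape + (3,)), GEOM)
        jac = jacobian_map(fld, mask=full_mask(GEOM))
        jac.values[...] = value
        return jac

    def test_equal_volumes_change_nothing(self):
        jac = self.make_jac(1.7)
        out = normalize_jac(jac, 1000.0, 1000.0)
        np.testing.assert_array_equal(out.values, jac.values)
        assert out.stage == "JAC-N"
        assert out.provenance["volume_ratio"] == 1.0

    def test_uniform_scaling_phantom_normalizes_to_unity(self):
        from lungdeform import DeformationModel, make_phantom

        s = 0.9
        subj = make_phantom(DeformationModel(affine_scale=(s, s, s),
                                             amplitude=0.0, seed=4))
        fld = true_field(subj.model, subj.expiration.geometry)
        jac = jacobian_map(fld, mask=subj.lung_mask_exp)
        jacn = normalize_jac(jac, lung_volume(subj.lung_mask_insp),
                             lung_volume(subj.lung_mask_exp))
        lung = subj.lung_mask_exp.astype_bool()
        np.testing.assert_allclose(jacn.values[lung], 1.0, atol=0.02)
        jacnl = log_jac(jacn)
        np.testing.assert_allclose(jacnl.values[lung], 0.0, atol=0.02)

    def test_log_trivials_and_roundtrip(self):
        jacn = normalize_jac(self.make_jac(1.0), 1.0, 1.0)
        np.testing.assert_allclose(log_jac(jacn).values, 0.0, atol=1e-15)
        jacn_e = normalize_jac(self.make_jac(np.e), 1.0, 1.0)
        np.testing.assert_allclose(log_jac(jacn_e).values, 1.0, atol=1e-12)
        rng = np.random.default_rng(1)
        jacn.values = rng.uniform(0.2, 3.0, GEOM.shape)
        np.testing.assert_allclose(np.exp(log_jac(jacn).values), jacn.values,
                                   atol=1e-12)

    def test_stage_transitions_enforced(self):
        jac = self.make_jac()
        with pytest.raises(ValueError, match="positive"):
            normalize_jac(jac, -1.0, 1.0)
        jacn = normalize_jac(jac, 1.0, 1.0)
        with pytest.raises(ValueError, match="transition"):
            normalize_jac(jacn, 1.0, 1.0)
        with pytest.raises(ValueError, match="JAC-N"):
            log_jac(jac)


class TestCommonSpace:
    def make_jacnl(self, values, geom=GEOM, mask=None):
        fld = DisplacementField(np.zeros(geom.shape + (3,)), geom)
        jac = jacobian_map(fld, mask=mask or full_mask(geom))
        jacnl = log_jac(normalize_jac(jac, 1.0, 1.0))
        jacnl.values = np.asarray(values, dtype=float)
        return jacnl

    def test_identity_affine_same_grid_is_identity(self):
        rng = np.random.default_rng(0)
        jacnl = self.make_jacnl(rng.normal(size=GEOM.shape))
        out = to_common_space(jacnl, AffineTransform.identity(), GEOM,
                              full_mask(GEOM))
        inside = out.mask.astype_bool()
        np.testing.assert_allclose(out.values[inside], jacnl.values[inside],
                                   atol=1e-12)
        assert out.stage == "JAC-NLC"

    def test_constant_map_transports_to_constant(self):
        jacnl = self.make_jacnl(np.full(GEOM.shape, -0.2))
        aff = AffineTransform(np.diag([1.1, 0.9, 1.05]), (2.0, -1.0, 0.5))
        out = to_common_space(jacnl, aff, GEOM, full_mask(GEOM))
        inside = out.mask.astype_bool()
        assert inside.sum() > 0
        np.testing.assert_allclose(out.values[inside], -0.2, atol=1e-12)

    def test_against_pointwise_resampling_oracle(self):
        # brute force: evaluate the affine per voxel and trilinearly
        # interpolate by hand with RegularGridInterpolator
        from scipy.interpolate import RegularGridInterpolator

        rng = np.random.default_rng(3)
        vals = rng.normal(size=GEOM.shape)
        jacnl = self.make_jacnl(vals)
        aff = AffineTransform(np.diag([1.08, 0.95, 1.02]), (1.5, -2.0, 0.7))
        out = to_common_space(jacnl, aff, GEOM, full_mask(GEOM))

        axes = [np.arange(n) * s for n, s in zip(GEOM.shape, GEOM.spacing)]
        interp = RegularGridInterpolator(axes, vals, bounds_error=False,
                                         fill_value=0.0)
        xs, ys, zs = GEOM.world_coordinates()
        pts = aff.apply(np.stack([xs, ys, zs], axis=-1).reshape(-1, 3))
        expect = interp(pts).reshape(GEOM.shape)
        inside = out.mask.astype_bool()
        np.testing.assert_allclose(out.values[inside], expect[inside], atol=1e-8)

    def test_determinant_rescaling_flag(self):
        jacnl = self.make_jacnl(np.full(GEOM.shape, -0.2))
        aff = AffineTransform(np.diag([2.0, 1.0, 1.0]), (0, 0, 0))
        out = to_common_space(jacnl, aff, GEOM, full_mask(GEOM),
                              rescale_by_determinant=True)
        inside = out.mask.astype_bool()
        np.testing.assert_allclose(out.values[inside], -0.4, atol=1e-12)


class TestGroupMapsAndEndpoints:
    def const_map(self, value, geom=GEOM):
        fld = DisplacementField(np.zeros(geom.shape + (3,)), geom)
        jac = jacobian_map(fld, mask=full_mask(geom))
        jacnl = log_jac(normalize_jac(jac, 1.0, 1.0))
        jacnl.values[...] = value
        return to_common_space(jacnl, AffineTransform.identity(), geom,
                               full_mask(geom))

    def test_single_map_average_is_itself(self):
        m = self.const_map(-0.1)
        avg = group_average([m], min_coverage=1)
        inside = avg.coverage.astype_bool()
        np.testing.assert_allclose(avg.values[inside], -0.1)
        assert avg.n_subjects == 1

    def test_two_constant_maps_average(self):
        avg = group_average([self.const_map(-0.1), self.const_map(-0.3)])
        inside = avg.coverage.astype_bool()
        np.testing.assert_allclose(avg.values[inside], -0.2, atol=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            group_average([])

    def test_axis_projection_constant_and_single_slice(self):
        avg = group_average([self.const_map(0.7)])
        proj = axis_projection(avg, "z")
        np.testing.assert_allclose(proj[np.isfinite(proj)], 0.7)
        # single covered slice: projection equals that slice
        vals = np.zeros(GEOM.shape)
        vals[:, :, 5] = 1.5
        cov = np.zeros(GEOM.shape, dtype=np.uint8)
        cov[:, :, 5] = 1
        avg2 = GroupAverageMap(vals, "g", 1, BinaryMask(cov, GEOM), GEOM)
        proj2 = axis_projection(avg2, "z")
        np.testing.assert_allclose(proj2, 1.5)

    def test_axis_projection_matches_per_line_mean(self, oracle_analysis):
        _, _, art = oracle_analysis
        haj = art["haj"]
        proj = axis_projection(haj, "y")
        cov = haj.coverage.astype_bool()
        for i in (10, 20, 30):
            for k in (10, 24, 38):
                line = cov[i, :, k]
                if line.any():
                    assert proj[i, k] == pytest.approx(haj.values[i, line, k].mean())
                else:
                    assert np.isnan(proj[i, k])

    def test_jac_mean_absolute_of_signed_mean(self):
        m = self.const_map(-0.2)
        assert jac_mean(m) == pytest.approx(0.2)
        assert jac_mean(self.const_map(0.0)) == 0.0
        # the mean-of-absolute variant differs on mixed-sign maps
        mixed = self.const_map(0.0)
        mixed.values[:12] = 0.3
        mixed.values[12:] = -0.3
        assert jac_mean(mixed, method="signed") == pytest.approx(0.0, abs=0.01)
        assert jac_mean(mixed, method="absolute") == pytest.approx(0.3, abs=0.01)

    def test_jac_mean_empty_region_rejected(self):
        m = self.const_map(-0.2)
        empty = BinaryMask(np.zeros(GEOM.shape, dtype=np.uint8), GEOM)
        with pytest.raises(ValueError, match="empty"):
            jac_mean(m, mask=empty)

    def test_marked_mask_trivials_and_monotone_cutoff(self):
        assert marked_deformation_mask(self.const_map(0.0)).voxel_count == 0
        assert (marked_deformation_mask(self.const_map(-0.2)).voxel_count
                == np.prod(GEOM.shape))
        rng = np.random.default_rng(2)
        m = self.const_map(0.0)
        m.values = rng.normal(scale=0.2, size=GEOM.shape)
        prev = None
        for cutoff in (0.10, 0.15, 0.20):
            cur = marked_deformation_mask(m, cutoff=cutoff).astype_bool()
            if prev is not None:
                assert np.all(prev >= cur)  # raising the cutoff never grows it
            prev = cur

    def test_healthy_template_trivials(self):
        haj_zero = group_average([self.const_map(0.0)])
        with pytest.raises(ValueError, match="empty"):
            healthy_template(haj_zero)
        haj = group_average([self.const_map(-0.2)])
        tmpl = healthy_template(haj)
        np.testing.assert_array_equal(tmpl.data, haj.coverage.data)

    def test_template_concentrates_in_peripheral_shell(self, oracle_analysis):
        subjects, _, art = oracle_analysis
        tmpl = art["template"]
        common = next(s for s in subjects
                      if s.subject_id == art["common_subject"])
        geom = tmpl.geometry
        xs, ys, zs = geom.world_coordinates()
        rel = (np.stack([xs, ys, zs], axis=-1)
               - np.asarray(common.model.center)) / np.asarray(common.model.lung_radii)
        rn = np.sqrt(np.sum(rel**2, axis=-1))
        inside = tmpl.astype_bool()
        assert inside.sum() > 0
        assert np.mean(rn[inside] > common.model.shell_fraction) >= 0.70

    def test_controls_shrink_more_than_ipf_in_shell(self, oracle_analysis):
        # healthy peripheral lung deforms more: HAJ is more negative than
        # IAJ on most of the shell
        subjects, _, art = oracle_analysis
        haj, iaj = art["haj"], art["iaj"]
        common = next(s for s in subjects
                      if s.subject_id == art["common_subject"])
        geom = haj.geometry
        xs, ys, zs = geom.world_coordinates()
        rel = (np.stack([xs, ys, zs], axis=-1)
               - np.asarray(common.model.center)) / np.asarray(common.model.lung_radii)
        rn = np.sqrt(np.sum(rel**2, axis=-1))
        shell = (haj.coverage.astype_bool() & iaj.coverage.astype_bool()
                 & (rn > common.model.shell_fraction))
        assert shell.sum() > 100
        assert np.mean(iaj.values[shell] - haj.values[shell] >= 0) > 0.80


class TestDice:
    def as_mask(self, arr):
        arr = np.asarray(arr, dtype=np.uint8)
        geom = Geometry(arr.shape, (1.0, 1.0, 1.0))
        return BinaryMask(arr, geom)

    def test_identical_masks_give_one(self):
        m = self.as_mask(np.ones((4, 4, 4)))
        br = dice_to_template(m, m)
        assert br.dice == 1.0 and br.fn == 0 and br.fp == 0

    def test_printed_formula_example(self):
        # TP=2, FN=1, FP=1 -> 2*2 / (2*2 + 1 + 1) = 2/3
        subj = np.zeros((4, 4, 4)); tmpl = np.zeros((4, 4, 4))
        subj[0, 0, :3] = 1
        tmpl[0, 0, 1:4] = 1
        br = dice_to_template(self.as_mask(subj), self.as_mask(tmpl))
        assert (br.tp, br.fn, br.fp) == (2, 1, 1)
        assert br.dice == pytest.approx(2 / 3)

    def test_both_empty_is_missing_not_zero(self):
        e = self.as_mask(np.zeros((4, 4, 4)))
        assert np.isnan(dice_to_template(e, e).dice)

    def test_random_pairs_match_exhaustive_counting(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a = rng.uniform(size=(8, 8, 8)) < 0.3
            b = rng.uniform(size=(8, 8, 8)) < 0.3
            br = dice_to_template(self.as_mask(a), self.as_mask(b))
            # exhaustive voxel-by-voxel counting oracle
            tp = fn = fp = 0
            for i in range(8):
                for j in range(8):
                    for k in range(8):
                        if a[i, j, k] and b[i, j, k]:
                            tp += 1
                        elif b[i, j, k]:
                            fn += 1
                        elif a[i, j, k]:
                            fp += 1
            assert (br.tp, br.fn, br.fp) == (tp, fn, fp)
            if tp + fn + fp:
                assert br.dice == pytest.approx(2 * tp / (2 * tp + fn + fp))
                # Dice-IoU identity and symmetry
                assert br.iou == pytest.approx(br.dice / (2 - br.dice))
                rev = dice_to_template(self.as_mask(b), self.as_mask(a))
                assert rev.dice == pytest.approx(br.dice)
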