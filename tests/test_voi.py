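import numpy as np
import pytest
from scipy import ndimage

from conftest import ball_mask, box_mask
from y90dose.constants import CONSTANTS
from y90dose.errors import (ConvergenceError, GridMismatchError,
                            InconsistencyError, InvalidInputError,
                            ZeroVolumeError)
from y90dose.grid import CountImage, ImageGrid, Mask, integer_shift
from y90dose.voi import (BooleanOp, Role, SegmentationSet,
                         adaptive_threshold_voi, build_segmentation_set,
                         left_lung_total_counts, lung_mass_from_ct,
                         mask_combine, two_voi_measure)


class TestMaskCombine:
    def test_union_is_idempotent(self, random_masks):
        a = random_masks[0]
        assert (mask_combine(a, a, BooleanOp.UNION).data == a.data).all()

    def test_disjoint_union_adds_volumes(self, small_grid):
        a = box_mask(small_grid, (0, 0, 0), (3, 3, 3))
        b = box_mask(small_grid, (6, 6, 6), (9, 9, 9))
        u = mask_combine(a, b, "UNION")
        assert u.n_voxels == a.n_voxels + b.n_voxels

    def test_subtract_on_toy_grid(self):
        # 3x3x1: A = left two columns (6 voxels), B = top row (3) -> 4 left
        g = ImageGrid((3, 3, 1), (1, 1, 1))
        a = np.zeros((3, 3, 1), bool); a[:, :2] = True
        b = np.zeros((3, 3, 1), bool); b[0, :] = True
        out = mask_combine(Mask(g, a), Mask(g, b), BooleanOp.SUBTRACT)
        assert out.n_voxels == 4

    def test_boolean_algebra_laws_on_random_masks(self, random_masks):
        a, b, _ = random_masks
        union = mask_combine(a, b, "UNION")
        inter = mask_combine(a, b, "INTERSECT")
        # inclusion-exclusion
        assert a.n_voxels + b.n_voxels == union.n_voxels + inter.n_voxels
        # De Morgan: not(A | B) == notA & notB
        not_a = Mask(a.grid, ~a.data)
        not_b = Mask(b.grid, ~b.data)
        lhs = ~union.data
        rhs = mask_combine(not_a, not_b, "INTERSECT").data
        assert (lhs == rhs).all()

    def test_grid_mismatch_rejected(self, small_grid):
        other = ImageGrid((12, 12, 12), (4.0, 4.0, 4.0), frame_id="other")
        a = box_mask(small_grid, (0, 0, 0), (2, 2, 2))
        b = Mask(other, np.ones(other.shape, bool))
        with pytest.raises(GridMismatchError):
            mask_combine(a, b, "UNION")


class TestAdaptiveThreshold:
    def test_unblurred_uniform_sphere_is_recovered_exactly(self, small_grid):
        sphere = ball_mask(small_grid, (6, 6, 6), 3.2)
        img = CountImage(small_grid, sphere.data * 100.0)
        out = adaptive_threshold_voi(img, sphere)
        assert (out.data == sphere.data).all()

    def test_blurred_sphere_volume_matches_ct_within_one_voxel(self):
        g = ImageGrid((40, 40, 40), (2.0, 2.0, 2.0))
        sphere = ball_mask(g, (20, 20, 20), 7.5)
        img_vals = ndimage.gaussian_filter(sphere.data * 1000.0,
                                           sigma=7.0 / 2.355 / 2.0)
        out = adaptive_threshold_voi(CountImage(g, img_vals), sphere)
        assert abs(out.n_voxels - sphere.n_voxels) <= 1

    def test_all_zero_image_fails_to_converge(self, small_grid):
        sphere = ball_mask(small_grid, (6, 6, 6), 3)
        img = CountImage(small_grid, np.zeros(small_grid.shape))
        with pytest.raises(ConvergenceError):
            adaptive_threshold_voi(img, sphere)

    def test_exclusion_mask_is_respected(self, small_grid):
        sphere = ball_mask(small_grid, (6, 6, 6), 3.2)
        core = ball_mask(small_grid, (6, 6, 6), 1.2, name="core")
        img = CountImage(small_grid, sphere.data * 50.0)
        out = adaptive_threshold_voi(img, sphere, exclude=core)
        assert not (out.data & core.data).any()


class TestTwoVoiMeasure:
    def test_matches_single_voi_when_masks_coincide(self, small_grid):
        m = box_mask(small_grid, (2, 2, 2), (8, 8, 8))
        img = CountImage(small_grid, np.full(small_grid.shape, 3.0))
        c = two_voi_measure(img, m, m)
        assert c.counts == pytest.approx(img.counts_in(m))
        assert c.volume_ml == pytest.approx(m.volume_ml)

    def test_counts_follow_the_shifted_nm_mask(self, small_grid):
        ct = box_mask(small_grid, (2, 2, 2), (8, 8, 6))
        rng = np.random.default_rng(7)
        truth = np.zeros(small_grid.shape)
        truth[ct.data] = rng.random(ct.n_voxels) * 10
        shifted_img = CountImage(small_grid, integer_shift(truth, 2))
        nm = ct.shifted(2)
        c = two_voi_measure(shifted_img, nm, ct)
        assert c.counts == pytest.approx(truth.sum(), rel=1e-12)
        assert c.volume_ml == pytest.approx(ct.volume_ml)

    def test_mass_is_volume_times_density(self, unit_grid):
        m = box_mask(unit_grid, (0, 0, 0), (10, 10, 10))  # 1000 voxels = 1000 mL
        img = CountImage(unit_grid, np.ones(unit_grid.shape))
        c = two_voi_measure(img, m, m, density=1.05)
        assert c.volume_ml == pytest.approx(1000.0)
        assert c.mass_kg == pytest.approx(1.05)

    def test_empty_ct_mask_rejected(self, small_grid):
        img = CountImage(small_grid, np.ones(small_grid.shape))
        empty = Mask(small_grid, np.zeros(small_grid.shape, bool))
        full = Mask(small_grid, np.ones(small_grid.shape, bool))
        with pytest.raises(ZeroVolumeError):
            two_voi_measure(img, full, empty)


def _segmentation_fixture(unit_grid):
    """Worked compartment example: 1500 mL liver, 100 mL lesion, 50 mL
    non-target, PL-in-liver 900 mL; counts PL 1e6 with 4e5 in the lesion."""
    liver = box_mask(unit_grid, (0, 0, 0), (15, 10, 10), name="liver")      # 1500
    lesion = box_mask(unit_grid, (0, 0, 0), (4, 5, 5), name="lesion_1")     # 100
    non_target = box_mask(unit_grid, (10, 5, 5), (12, 10, 5 + 5), name="nt")  # 50
    pl = box_mask(unit_grid, (0, 0, 0), (9, 10, 10), name="pl")             # 900, in liver
    vals = np.zeros(unit_grid.shape)
    lesion_vox = lesion.n_voxels
    vals[lesion.data] = 4e5 / lesion_vox
    rest = pl.data & ~lesion.data
    vals[rest] = 6e5 / rest.sum()
    img = CountImage(unit_grid, vals)
    return img, liver, lesion, non_target, pl


class TestBuildSegmentationSet:
    def test_worked_volume_and_count_bookkeeping(self, unit_grid):
        img, liver, lesion, non_target, pl = _segmentation_fixture(unit_grid)
        seg = build_segmentation_set(
            img, voi_ct_whole_liver=liver, voi_ct_lesions=[lesion],
            voi_ct_non_target=non_target, voi_nm_perfused_liver=pl,
            voi_nm_lesions=[lesion])
        assert seg.get("ntl").volume_ml == pytest.approx(1350.0)
        assert seg.get("pntl").volume_ml == pytest.approx(800.0)
        assert seg.vf == pytest.approx(800.0 / 1350.0, abs=5e-4)  # 0.593
        assert seg.get("pntl").counts == pytest.approx(6e5)
        assert seg.get("lesion_1").counts == pytest.approx(4e5)

    def test_no_lesions_gives_vf_one(self, unit_grid):
        liver = box_mask(unit_grid, (0, 0, 0), (10, 10, 10), name="liver")
        img = CountImage(unit_grid, liver.data * 5.0)
        seg = build_segmentation_set(img, voi_ct_whole_liver=liver)
        assert seg.vf == pytest.approx(1.0)
        assert seg.get("ntl").counts == pytest.approx(seg.get("perfused_liver").counts)

    def test_count_conservation_is_exact(self, unit_grid):
        img, liver, lesion, non_target, pl = _segmentation_fixture(unit_grid)
        seg = build_segmentation_set(
            img, voi_ct_whole_liver=liver, voi_ct_lesions=[lesion],
            voi_nm_perfused_liver=pl, voi_nm_lesions=[lesion])
        lesions = sum(c.counts for c in seg.by_role(Role.LESION_CT))
        assert seg.get("pntl").counts + lesions == seg.get("perfused_liver").counts

    def test_lesion_counts_exceeding_liver_counts_rejected(self, unit_grid):
        liver = box_mask(unit_grid, (0, 0, 0), (10, 10, 10), name="liver")
        lesion = box_mask(unit_grid, (0, 0, 0), (5, 5, 5), name="lesion_1")
        pl = box_mask(unit_grid, (0, 0, 0), (2, 2, 2), name="pl")
        vals = np.zeros(unit_grid.shape)
        vals[lesion.data] = 10.0
        img = CountImage(unit_grid, vals)
        with pytest.raises(InconsistencyError):
            build_segmentation_set(img, voi_ct_whole_liver=liver,
                                   voi_ct_lesions=[lesion],
                                   voi_nm_perfused_liver=pl,
                                   voi_nm_lesions=[lesion])

    def test_small_lesion_triggers_reliability_warning(self, small_grid):
        liver = ball_mask(small_grid, (6, 6, 6), 5, name="liver")
        tiny = ball_mask(small_grid, (6, 6, 6), 1.1, name="tiny")  # ~2 voxels wide
        img = CountImage(small_grid, liver.data * 2.0)
        with pytest.warns(UserWarning, match="< 2"):
            seg = build_segmentation_set(img, voi_ct_whole_liver=liver,
                                         voi_ct_lesions=[tiny],
                                         voi_nm_lesions=[tiny])
        assert seg.warnings_

    def test_json_round_trip(self, unit_grid):
        img, liver, lesion, non_target, pl = _segmentation_fixture(unit_grid)
        seg = build_segmentation_set(
            img, voi_ct_whole_liver=liver, voi_ct_lesions=[lesion],
            voi_nm_perfused_liver=pl, voi_nm_lesions=[lesion])
        back = SegmentationSet.from_json(seg.to_json())
        assert back.vf == pytest.approx(seg.vf)
        assert back.get("pntl").counts == pytest.approx(seg.get("pntl").counts)


class TestLungHelpers:
    def test_left_lung_proportional_extrapolation(self):
        assert left_lung_total_counts(1e4, 1200, 3000) == pytest.approx(25000)

    def test_total_equal_to_left_is_identity(self):
        assert left_lung_total_counts(7000, 2800, 2800) == pytest.approx(7000)

    def test_zero_left_volume_rejected(self):
        with pytest.raises(InvalidInputError):
            left_lung_total_counts(5000, 0, 3000)

    @pytest.mark.parametrize("volume,density,expected", [
        (3333.3, 0.3, 0.99999),
        (1000.0, 0.3, 0.3),
        (4000.0, 0.26, 1.04),
    ])
    def test_lung_mass_from_ct(self, volume, density, expected):
        assert lung_mass_from_ct(volume, density) == pytest.approx(expected, rel=1e-4)

    def test_nonpositive_lung_volume_rejected(self):
        with pytest.raises(InvalidInputError):
            lung_mass_from_ct(0.0)
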