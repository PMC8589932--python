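import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from y90dose.errors import InvalidInputError, UndefinedLSFError
from y90dose.shunt import (LungCoverage, PlanarRoiCounts, PlanarView,
                           ShuntAssessment, ShuntClass, assess_from_planar,
                           classify_shunt, conjugate_mean,
                           estimated_lung_counts, liver_activity, lsf_planar,
                           lsf_star, lsf_tomo, lsf_tomo_from_left_lung,
                           lung_activity, lung_dose, net_counts,
                           read_planar_roi_csv, resin_prescription_rule)


class TestNetCounts:
    def test_background_subtraction_with_buijs_factor(self):
        roi = PlanarRoiCounts(10000, 400, 2000, 100)
        # 10000 - (2000/100) * 400 * 0.5
        assert net_counts(roi) == pytest.approx(6000)

    def test_zero_background_leaves_raw_counts(self):
        roi = PlanarRoiCounts(5000, 400, 0, 100)
        assert net_counts(roi) == pytest.approx(5000)

    def test_negative_result_clamped_with_warning(self):
        roi = PlanarRoiCounts(100, 400, 2000, 100)
        with pytest.warns(UserWarning, match="clamped"):
            assert net_counts(roi) == 0.0

    def test_zero_background_area_rejected(self):
        with pytest.raises(InvalidInputError):
            PlanarRoiCounts(100, 400, 2000, 0)


class TestConjugateMean:
    def test_geometric_mean(self):
        assert conjugate_mean(9000, 4000) == pytest.approx(6000)

    @given(st.floats(1, 1e7))
    def test_identical_views_are_fixed_points(self, x):
        assert conjugate_mean(x, x) == pytest.approx(x)

    def test_zero_view_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert conjugate_mean(0, 5000) == 0.0


class TestLsfPlanar:
    def test_basic_ratio(self):
        assert lsf_planar(1000, 9000) == pytest.approx(0.10)

    def test_no_lung_counts_gives_zero(self):
        assert lsf_planar(0, 123456) == 0.0

    def test_undefined_when_both_zero(self):
        with pytest.raises(UndefinedLSFError):
            lsf_planar(0, 0)


class TestLungDose:
    def test_standard_lung_mass_example(self):
        assert lung_dose(2.0, 0.05, 1.0) == pytest.approx(4.975)

    def test_worst_case_small_lung_at_three_gbq_respects_30_gy(self):
        d = lung_dose(3.0, 0.10, 0.5)
        assert d == pytest.approx(29.85)
        assert d <= 30.0

    def test_zero_shunt_gives_zero_dose(self):
        assert lung_dose(5.0, 0.0, 1.0) == 0.0

    @given(a=st.floats(0.1, 10), lsf=st.floats(0, 0.5), m=st.floats(0.3, 2.0))
    def test_linearity_in_activity_and_lsf_inverse_in_mass(self, a, lsf, m):
        base = lung_dose(a, lsf, m)
        assert lung_dose(2 * a, lsf, m) == pytest.approx(2 * base, rel=1e-12)
        assert lung_dose(a, lsf, 2 * m) == pytest.approx(base / 2, rel=1e-12)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(InvalidInputError):
            lung_dose(2.0, 0.05, 0.0)


class TestLsfStar:
    def test_boundary_value_is_0p037(self):
        assert round(lsf_star(0.10), 3) == 0.037

    def test_zero_maps_to_zero(self):
        assert lsf_star(0.0) == 0.0

    def test_divisor_is_2p7(self):
        assert lsf_star(0.08) == pytest.approx(0.08 / 2.7)

    @given(st.floats(1e-6, 0.999))
    def test_star_is_always_smaller_than_planar(self, x):
        assert lsf_star(x) < x

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            lsf_star(1.0)


class TestClassifyShunt:
    @pytest.mark.parametrize("lsf,expected", [
        (0.0, ShuntClass.NONE),
        (0.05, ShuntClass.NON_RELEVANT),
        (0.10, ShuntClass.NON_RELEVANT),   # strict '>' cut-off
        (0.1001, ShuntClass.SUBSTANTIAL),
        (0.12, ShuntClass.SUBSTANTIAL),
    ])
    def test_three_class_boundaries(self, lsf, expected):
        assert classify_shunt(lsf) is expected

    @given(st.floats(0, 0.99), st.floats(0, 0.99))
    def test_classification_is_monotone(self, a, b):
        order = [ShuntClass.NONE, ShuntClass.NON_RELEVANT, ShuntClass.SUBSTANTIAL]
        lo, hi = sorted([a, b])
        assert order.index(classify_shunt(lo)) <= order.index(classify_shunt(hi))


class TestEstimatedLungCounts:
    def test_inversion_formula(self):
        assert estimated_lung_counts(1e6, 0.037) == pytest.approx(38422, abs=1)

    def test_zero_star_means_no_lung_counts(self):
        assert estimated_lung_counts(5e5, 0.0) == 0.0

    def test_half_star_equals_liver_counts(self):
        assert estimated_lung_counts(1e6, 0.5) == pytest.approx(1e6)

    def test_star_of_one_rejected(self):
        with pytest.raises(InvalidInputError):
            estimated_lung_counts(1e6, 1.0)


class TestLiverActivity:
    def test_starred_mode(self):
        assert liver_activity(2.0, 0.0296, "STAR") == pytest.approx(1.9408)

    def test_zero_shunt_returns_everything(self):
        assert liver_activity(1.7, 0.0, "PLANAR_RAW") == 1.7

    def test_tomo_mode(self):
        assert liver_activity(1.5, 0.15, "TOMO") == pytest.approx(1.275)

    @given(a=st.floats(0.1, 10), lsf=st.floats(0, 0.99))
    def test_liver_plus_lung_conserves_total(self, a, lsf):
        assert liver_activity(a, lsf) + lung_activity(a, lsf) == pytest.approx(a, rel=1e-12)


class TestResinRule:
    @pytest.mark.parametrize("lsf,factor,contra", [
        (0.05, 1.0, False),
        (0.10, 1.0, False),
        (0.12, 0.8, False),
        (0.15, 0.6, False),    # boundary -> more conservative band
        (0.17, 0.6, False),
        (0.20, 0.0, True),     # boundary -> contraindicated
        (0.25, 0.0, True),
    ])
    def test_bands_and_boundaries(self, lsf, factor, contra):
        rule = resin_prescription_rule(lsf)
        assert rule["contraindicated"] is contra
        if not contra:
            assert rule["factor"] == factor


class TestLsfTomo:
    def test_ratio(self):
        assert lsf_tomo(25000, 975000) == pytest.approx(0.025)

    def test_zero_lung(self):
        assert lsf_tomo(0, 1e6) == 0.0

    def test_left_lung_route_combines_extrapolation_and_ratio(self):
        # left 1e4 counts over 1200/3000 mL -> 25000 total lung counts
        assert lsf_tomo_from_left_lung(1e4, 1200, 3000, 975000) == pytest.approx(0.025)

    def test_truncated_lung_field_of_view_refused(self):
        with pytest.raises(InvalidInputError, match="truncated"):
            lsf_tomo_from_left_lung(1e4, 1200, 3000, 975000,
                                    coverage=LungCoverage.TRUNCATED)

    def test_direct_whole_lung_voi_warns_about_scatter(self):
        with pytest.warns(UserWarning, match="scatter"):
            lsf_tomo_from_left_lung(25000, 3000, 3000, 975000,
                                    coverage=LungCoverage.WHOLE)


class TestAssessmentWorkflow:
    def _rois(self, lung_raw, liver_raw):
        mk = lambda raw, view: PlanarRoiCounts(raw, 400, 1000, 100, view)
        return ([mk(lung_raw, PlanarView.ANT), mk(lung_raw, PlanarView.POST)],
                [mk(liver_raw, PlanarView.ANT), mk(liver_raw, PlanarView.POST)])

    def test_full_planar_chain(self):
        lung, liver = self._rois(12000, 92000)
        a = assess_from_planar(lung, liver, a_total=2.0)
        # net: 12000-2000=10000 lung, 92000-2000=90000 liver -> LSF 0.10
        assert a.lsf_planar == pytest.approx(0.10)
        assert a.lsf_star == pytest.approx(0.037, abs=5e-4)
        assert a.shunt_class is ShuntClass.NON_RELEVANT
        assert a.lung_dose_gy == pytest.approx(49.75 * 2.0 * 0.10)

    def test_single_view_legacy_mode(self):
        lung, liver = self._rois(12000, 92000)
        a = assess_from_planar(lung[0], liver[0], a_total=1.0, conjugate=False)
        assert a.lsf_planar == pytest.approx(0.10)

    def test_inconsistent_star_value_rejected(self):
        with pytest.raises(InvalidInputError):
            ShuntAssessment(lsf_planar=0.10, lsf_star=0.09,
                            shunt_class=ShuntClass.NON_RELEVANT,
                            lung_mass_kg=1.0, lung_dose_gy=5.0)

    def test_json_round_trip(self):
        lung, liver = self._rois(12000, 92000)
        a = assess_from_planar(lung, liver, a_total=2.0)
        back = ShuntAssessment.from_json(a.to_json())
        assert back.lsf_planar == pytest.approx(a.lsf_planar)
        assert back.shunt_class is a.shunt_class


def test_planar_roi_csv_reader(tmp_path):
    csv = tmp_path / "rois.csv"
    csv.write_text(
        "view,organ,raw_counts,area_px,bckg_counts,bckg_area_px\n"
        "ANT,lung,12000,400,1000,100\n"
        "POST,lung,12000,400,1000,100\n"
        "ANT,liver,92000,400,1000,100\n"
        "POST,liver,92000,400,1000,100\n")
    rois = read_planar_roi_csv(csv)
    assert set(rois) == {"lung", "liver"}
    a = assess_from_planar(rois["lung"], rois["liver"], a_total=2.0)
    assert a.lsf_planar == pytest.approx(0.10)
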