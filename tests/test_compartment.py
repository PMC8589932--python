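import numpy as np
import pytest

from y90dose.compartment import (PlanFlag, SphereType, mean_dose,
                                 plan_options, subtraction_method)
from y90dose.errors import InvalidInputError
from y90dose.shunt import ShuntAssessment, classify_shunt, lsf_star, lung_dose
from y90dose.voi import CompartmentMeasure, Role, SegmentationSet


def make_seg(liver_counts, liver_mass, lesions, vf=0.8):
    """SegmentationSet from scalar bookkeeping (counts, mass_kg pairs)."""
    lesion_counts = sum(c for c, _ in lesions)
    lesion_mass = sum(m for _, m in lesions)
    lesion_vol = lambda m: m / 1.05 * 1e3
    comps = [
        CompartmentMeasure("whole_liver", Role.WHOLE_LIVER, liver_counts,
                           liver_mass / 1.05 * 1e3, liver_mass),
        CompartmentMeasure("perfused_liver", Role.PL, liver_counts,
                           liver_mass / 1.05 * 1e3, liver_mass),
    ]
    for i, (c, m) in enumerate(lesions, start=1):
        comps.append(CompartmentMeasure(f"lesion_{i}", Role.LESION_CT, c,
                                        lesion_vol(m), m))
    ntl_mass = liver_mass - lesion_mass
    comps.append(CompartmentMeasure("pntl", Role.PNTL,
                                    liver_counts - lesion_counts,
                                    ntl_mass / 1.05 * 1e3, ntl_mass))
    comps.append(CompartmentMeasure("ntl", Role.NTL,
                                    liver_counts - lesion_counts,
                                    ntl_mass / 1.05 * 1e3, ntl_mass))
    return SegmentationSet(comps, vf)


def partition_model_single_lesion(cf, n_t, m_t, n_ntl, m_ntl):
    """Independent oracle: classical partition model for one lesion.

    The liver activity A = CF (N_t + N_ntl) is split according to the
    tumour-to-normal uptake ratio r = (N_t/M_t)/(N_ntl/M_ntl):
    A_t = A r M_t / (r M_t + M_ntl), and doses are 49.75 A/M.
    """
    a = cf * (n_t + n_ntl)
    r = (n_t / m_t) / (n_ntl / m_ntl)
    a_t = a * r * m_t / (r * m_t + m_ntl)
    a_ntl = a - a_t
    return 49.75 * a_t / m_t, 49.75 * a_ntl / m_ntl


class TestMeanDose:
    def test_one_gbq_in_one_kg_gives_the_dose_constant(self):
        # CF and counts chosen so A_VOI = 1 GBq
        assert mean_dose(1e-6, 1e6, 1.0) == pytest.approx(49.75)

    def test_worked_example(self):
        assert mean_dose(5e-7, 8e5, 0.4) == pytest.approx(49.75)

    def test_zero_counts_zero_dose(self):
        assert mean_dose(5e-7, 0, 1.0) == 0.0

    def test_zero_mass_rejected(self):
        with pytest.raises(InvalidInputError):
            mean_dose(5e-7, 1e5, 0.0)


class TestSubtractionMethod:
    def test_two_lesion_worked_example(self):
        seg = make_seg(1e6, 1.5, [(3e5, 0.15), (1e5, 0.05)])
        results = {r.name: r for r in subtraction_method(seg, 5e-7)}
        # NTL: N 6e5, M 1.3 kg
        assert results["ntl"].mean_dose_gy == pytest.approx(
            49.75 * 5e-7 * 6e5 / 1.3, rel=1e-12)
        assert results["ntl"].mean_dose_gy == pytest.approx(11.48, abs=0.005)

    def test_no_lesions_ntl_equals_whole_liver_dose(self):
        seg = make_seg(1e6, 1.5, [])
        results = {r.name: r for r in subtraction_method(seg, 5e-7)}
        assert results["ntl"].mean_dose_gy == pytest.approx(
            results["whole_liver"].mean_dose_gy, rel=1e-12)

    @pytest.mark.parametrize("n_t,m_t,n_ntl,m_ntl", [
        (3e5, 0.2, 7e5, 1.3),
        (1e5, 0.05, 9e5, 1.6),
        (5e5, 0.5, 5e5, 1.0),
    ])
    def test_equivalent_to_partition_model_for_single_lesion(self, n_t, m_t, n_ntl, m_ntl):
        cf = 7.3e-7
        seg = make_seg(n_t + n_ntl, m_t + m_ntl, [(n_t, m_t)])
        results = {r.name: r for r in subtraction_method(seg, cf)}
        d_t, d_ntl = partition_model_single_lesion(cf, n_t, m_t, n_ntl, m_ntl)
        assert results["lesion_1"].mean_dose_gy == pytest.approx(d_t, rel=1e-12)
        assert results["ntl"].mean_dose_gy == pytest.approx(d_ntl, rel=1e-12)

    def test_count_conservation_across_compartments(self):
        seg = make_seg(1e6, 1.5, [(3e5, 0.15), (1e5, 0.05)])
        results = {r.name: r for r in subtraction_method(seg, 5e-7)}
        total = results["ntl"].activity_gbq + sum(
            results[f"lesion_{i}"].activity_gbq for i in (1, 2))
        assert total == pytest.approx(results["whole_liver"].activity_gbq, rel=1e-12)

    def test_absorbed_fraction_lowers_lesion_dose_only(self):
        seg = make_seg(1e6, 1.5, [(3e5, 0.15)])
        plain = {r.name: r for r in subtraction_method(seg, 5e-7)}
        phi = {r.name: r for r in subtraction_method(seg, 5e-7,
                                                     apply_absorbed_fraction=True)}
        assert phi["lesion_1"].mean_dose_gy < plain["lesion_1"].mean_dose_gy
        assert phi["ntl"].mean_dose_gy == pytest.approx(plain["ntl"].mean_dose_gy)
        assert phi["lesion_1"].absorbed_fraction_applied


def make_shunt(lsf_planar_value, lung_mass=1.0, a_ref=1.0):
    return ShuntAssessment(
        lsf_planar=lsf_planar_value, lsf_star=lsf_star(lsf_planar_value),
        shunt_class=classify_shunt(lsf_planar_value), lung_mass_kg=lung_mass,
        lung_dose_gy=lung_dose(a_ref, lsf_planar_value, lung_mass))


class TestPlanOptions:
    def make(self, vf=0.8, lsf=0.05, sphere=SphereType.GLASS,
             candidates=(1.0, 2.0, 3.0), prior=0.0):
        seg = make_seg(1e6, 1.5, [(3e5, 0.15)], vf=vf)
        cf_per_gbq = 1.0 / 1e6
        return plan_options(seg, cf_per_gbq, candidates, sphere,
                            make_shunt(lsf), cumulative_prior_lung_dose_gy=prior)

    def test_doses_scale_linearly_with_candidate_activity(self):
        opts = self.make(candidates=(1.0, 2.0))
        for d1, d2 in zip(opts[0].doses, opts[1].doses):
            assert d2.mean_dose_gy == pytest.approx(2 * d1.mean_dose_gy, rel=1e-12)
        assert opts[1].lung_dose_gy == pytest.approx(2 * opts[0].lung_dose_gy, rel=1e-12)

    def test_resin_band_suggests_20_percent_reduction(self):
        opts = self.make(lsf=0.12, sphere=SphereType.RESIN, candidates=(2.0,))
        assert PlanFlag.RESIN_REDUCE_20 in opts[0].flags
        assert opts[0].suggested_activity_gbq == pytest.approx(1.6)

    def test_resin_rule_ignored_for_glass(self):
        opts = self.make(lsf=0.12, sphere=SphereType.GLASS, candidates=(2.0,))
        assert PlanFlag.RESIN_REDUCE_20 not in opts[0].flags

    def test_vf_flag_present_below_threshold_absent_above(self):
        below = self.make(vf=0.35, candidates=(1.0,))[0]
        above = self.make(vf=0.55, candidates=(1.0,))[0]
        assert PlanFlag.VF_HIGH_DOSE_PERMISSIBLE in below.flags
        assert PlanFlag.VF_HIGH_DOSE_PERMISSIBLE not in above.flags

    def test_lung_limit_not_flagged_below_30_gy(self):
        opt = self.make(lsf=0.10, candidates=(3.0,))[0]
        assert opt.lung_dose_gy == pytest.approx(14.925)
        assert PlanFlag.LUNG_SINGLE_LIMIT not in opt.flags

    def test_lung_single_and_cumulative_limits_flagged(self):
        opt = self.make(lsf=0.15, candidates=(5.0,), prior=20.0)[0]
        assert opt.lung_dose_gy > 30
        assert PlanFlag.LUNG_SINGLE_LIMIT in opt.flags
        assert PlanFlag.LUNG_CUMULATIVE_LIMIT in opt.flags

    def test_empty_candidates_rejected(self):
        with pytest.raises(InvalidInputError):
            self.make(candidates=())
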