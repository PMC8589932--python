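"""Shared builder for synthetic case records used by reporting/CLI tests."""

from y90dose.compartment import subtraction_method
from y90dose.grid import Session
from y90dose.quantify import ActivityBasis, conversion_factor
from y90dose.reporting import SessionRecord
from y90dose.shunt import (ShuntAssessment, classify_shunt, lsf_star,
                           lung_dose)
from y90dose.voi import CompartmentMeasure, Role, SegmentationSet


def build_segmentation(liver_counts=1e6, lesion_counts=3e5,
                       liver_mass=1.5, lesion_mass=0.15, vf=0.85,
                       lesion_name="lesion_1") -> SegmentationSet:
    ml = lambda m: m / 1.05 * 1e3
    ntl_mass = liver_mass - lesion_mass
    comps = [
        CompartmentMeasure("whole_liver", Role.WHOLE_LIVER, liver_counts,
                           ml(liver_mass), liver_mass),
        CompartmentMeasure("perfused_liver", Role.PL, liver_counts,
                           ml(liver_mass), liver_mass),
        CompartmentMeasure(lesion_name, Role.LESION_CT, lesion_counts,
                           ml(lesion_mass), lesion_mass),
        CompartmentMeasure("pntl", Role.PNTL, liver_counts - lesion_counts,
                           ml(ntl_mass), ntl_mass),
        CompartmentMeasure("ntl", Role.NTL, liver_counts - lesion_counts,
                           ml(ntl_mass), ntl_mass),
    ]
    return SegmentationSet(comps, vf)


def build_session(session: Session, a_total: float = 2.0, lsf: float = 0.05,
                  rename_lesion: bool = False) -> SessionRecord:
    seg = build_segmentation(
        lesion_name="lesion_renamed" if rename_lesion else "lesion_1")
    n_total = seg.get("perfused_liver").counts  # no lung counts in this toy
    basis = (ActivityBasis.INTENDED_ACTIVITY if session is Session.PRE
             else ActivityBasis.NET_ADMINISTERED)
    cf = conversion_factor(a_total, n_total, basis, session)
    shunt = ShuntAssessment(lsf, lsf_star(lsf), classify_shunt(lsf), 1.0,
                            lung_dose(a_total, lsf, 1.0))
    doses = subtraction_method(seg, cf)
    return SessionRecord(session, shunt, cf, seg, doses)
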