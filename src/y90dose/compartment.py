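"""Compartmental mean absorbed dose and treatment-planning options.

The mean dose of a VOI is D = 49.75 · A_VOI / M_VOI with A_VOI = CF · N_VOI
(GBq) and M_VOI in kg.  Non-tumoural liver counts and mass are obtained by
subtracting lesion VOIs from the whole liver ("subtraction method"), which
for a single lesion is numerically equivalent to the classical partition
model.  Planning evaluates each candidate administered activity against the
lung dose limits (30 Gy single, 50 Gy cumulative), the resin-sphere LSF
reduction bands, the treated-volume-fraction rule (Vf < 0.40: whole-liver
mean-dose criterion not applicable) and the 2 cm small-lesion reliability
limit — as flags for the therapist, never refusals.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import pandas as pd

from .betakernel import absorbed_fraction_sphere
from .constants import CONSTANTS
from .errors import InvalidInputError
from .quantify import ConversionFactor, activity_of_voi
from .shunt import ShuntAssessment, lung_dose, resin_prescription_rule
from .voi import Role, SegmentationSet


class SphereType(str, enum.Enum):
    RESIN = "RESIN"
    GLASS = "GLASS"


class PlanFlag(str, enum.Enum):
    LUNG_SINGLE_LIMIT = "LUNG_SINGLE_LIMIT"
    LUNG_CUMULATIVE_LIMIT = "LUNG_CUMULATIVE_LIMIT"
    RESIN_REDUCE_20 = "RESIN_REDUCE_20"
    RESIN_REDUCE_40 = "RESIN_REDUCE_40"
    RESIN_CONTRAINDICATED = "RESIN_CONTRAINDICATED"
    VF_HIGH_DOSE_PERMISSIBLE = "VF_HIGH_DOSE_PERMISSIBLE"
    SMALL_LESION = "SMALL_LESION"


def mean_dose(cf: ConversionFactor | float, n_voi: float, m_voi_kg: float,
              dose_constant: float = CONSTANTS.dose_constant,
              absorbed_fraction: float = 1.0) -> float:
    """Mean absorbed dose (Gy): dose_constant · CF · N_VOI / M_VOI · phi."""
    if m_voi_kg <= 0:
        raise InvalidInputError("VOI mass must be > 0")
    if n_voi < 0:
        raise InvalidInputError("VOI counts must be >= 0")
    if not 0.0 < absorbed_fraction <= 1.0:
        raise InvalidInputError("absorbed fraction must lie in (0, 1]")
    return dose_constant * float(cf) * n_voi / m_voi_kg * absorbed_fraction


@dataclass
class DoseResult:
    """Mean-dose outcome for one compartment."""

    name: str
    role: Role
    activity_gbq: float
    mass_kg: float
    mean_dose_gy: float
    absorbed_fraction_applied: bool = False
    flags: list = field(default_factory=list)

    def __post_init__(self):
        self.role = Role(self.role)
        if self.mean_dose_gy < 0:
            raise InvalidInputError("mean dose must be >= 0")

    def scaled(self, factor: float) -> "DoseResult":
        return DoseResult(self.name, self.role, self.activity_gbq * factor,
                          self.mass_kg, self.mean_dose_gy * factor,
                          self.absorbed_fraction_applied, list(self.flags))


def subtraction_method(seg: SegmentationSet, cf: ConversionFactor | float,
                       apply_absorbed_fraction: bool = False,
                       dose_constant: float = CONSTANTS.dose_constant) -> list:
    """Mean doses for every compartment of a segmentation set.

    Lesion doses use NM counts with CT mass by default; perfused-lesion
    (NM-volume) results are reported alongside so both conventions appear.
    The non-tumoural liver dose comes in two flavours: the perfused
    non-tumoural dose (PNTL counts over PNTL mass) and the whole
    non-tumoural dose (PNTL counts over the whole NTL mass), the latter
    being the planning parameter averaged over the whole functional organ.

    With ``apply_absorbed_fraction`` the lesion doses are multiplied by the
    sphere-equivalent absorbed fraction; it is off by default because the
    canonical formula mandates phi = 1 and treats the size dependence as a
    known systematic.
    """
    results = []
    for comp in seg.compartments:
        phi_applied = False
        phi = 1.0
        if apply_absorbed_fraction and comp.role in (Role.LESION_CT,
                                                     Role.LESION_PERFUSED,
                                                     Role.THROMBUS):
            phi = absorbed_fraction_sphere(comp.volume_ml) if comp.volume_ml > 0 else 1.0
            phi_applied = True
        if comp.mass_kg <= 0:
            continue
        flags = []
        if comp.role in (Role.LESION_CT, Role.LESION_PERFUSED) and \
                comp.equivalent_sphere_diameter_cm() < CONSTANTS.min_reliable_lesion_diameter:
            flags.append(PlanFlag.SMALL_LESION)
        results.append(DoseResult(
            name=comp.name, role=comp.role,
            activity_gbq=activity_of_voi(cf, comp.counts),
            mass_kg=comp.mass_kg,
            mean_dose_gy=mean_dose(cf, comp.counts, comp.mass_kg, dose_constant, phi),
            absorbed_fraction_applied=phi_applied, flags=flags))
    return results


def dose_results_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [{"name": r.name, "role": r.role.value, "activity_GBq": r.activity_gbq,
          "mass_kg": r.mass_kg, "mean_dose_Gy": r.mean_dose_gy,
          "absorbed_fraction_applied": r.absorbed_fraction_applied,
          "flags": ";".join(f.value for f in r.flags)}
         for r in results])


@dataclass
class PlanOption:
    """Dosimetry for one candidate administered activity, with rule flags."""

    candidate_activity_gbq: float
    doses: list
    lung_dose_gy: float
    flags: list = field(default_factory=list)
    suggested_activity_gbq: float | None = None
    notes: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = dose_results_frame(self.doses)
        df.insert(0, "candidate_GBq", self.candidate_activity_gbq)
        return df


def plan_options(seg: SegmentationSet, cf_per_gbq: ConversionFactor | float,
                 candidate_activities, sphere_type: SphereType | str,
                 shunt: ShuntAssessment,
                 cumulative_prior_lung_dose_gy: float = 0.0,
                 dose_constant: float = CONSTANTS.dose_constant) -> list:
    """Dosimetric options for several candidate activities.

    ``cf_per_gbq`` is the conversion factor normalised to 1 GBq total
    activity (CF computed with A_total = 1), so every dose scales linearly
    with the candidate.  The lung dose uses the planar LSF with the
    assessment's lung mass — the methodology the historical limits were
    derived with.
    """
    sphere_type = SphereType(sphere_type)
    candidates = [float(a) for a in candidate_activities]
    if not candidates:
        raise InvalidInputError("at least one candidate activity is required")
    if any(a <= 0 for a in candidates):
        raise InvalidInputError("candidate activities must be > 0")

    per_gbq = subtraction_method(seg, cf_per_gbq, dose_constant=dose_constant)
    resin = resin_prescription_rule(shunt.lsf_planar)

    options = []
    for a in candidates:
        flags, notes = [], []
        suggested = None
        doses = [r.scaled(a) for r in per_gbq]
        ld = lung_dose(a, shunt.lsf_planar, shunt.lung_mass_kg, dose_constant)
        if ld > CONSTANTS.lung_dose_limit_single:
            flags.append(PlanFlag.LUNG_SINGLE_LIMIT)
            notes.append(f"lung dose {ld:.1f} Gy exceeds "
                         f"{CONSTANTS.lung_dose_limit_single:.0f} Gy single-administration limit")
        if cumulative_prior_lung_dose_gy + ld > CONSTANTS.lung_dose_limit_cumulative:
            flags.append(PlanFlag.LUNG_CUMULATIVE_LIMIT)
            notes.append(
                f"cumulative lung dose {cumulative_prior_lung_dose_gy + ld:.1f} Gy exceeds "
                f"{CONSTANTS.lung_dose_limit_cumulative:.0f} Gy limit")
        if sphere_type is SphereType.RESIN:
            if resin["contraindicated"]:
                flags.append(PlanFlag.RESIN_CONTRAINDICATED)
                notes.append("resin spheres contraindicated at this LSF")
            elif resin["factor"] == 0.8:
                flags.append(PlanFlag.RESIN_REDUCE_20)
                suggested = a * resin["factor"]
                notes.append(f"resin rule suggests 20% reduction: {suggested:.2f} GBq")
            elif resin["factor"] == 0.6:
                flags.append(PlanFlag.RESIN_REDUCE_40)
                suggested = a * resin["factor"]
                notes.append(f"resin rule suggests 40% reduction: {suggested:.2f} GBq")
        if seg.vf < CONSTANTS.vf_high_dose_threshold:
            flags.append(PlanFlag.VF_HIGH_DOSE_PERMISSIBLE)
            notes.append(
                f"Vf = {seg.vf:.2f} < {CONSTANTS.vf_high_dose_threshold:.2f}: whole-liver "
                "mean-dose criterion not applicable, arbitrarily high dosage permissible")
        for r in doses:
            if PlanFlag.SMALL_LESION in r.flags and PlanFlag.SMALL_LESION not in flags:
                flags.append(PlanFlag.SMALL_LESION)
                notes.append(f"lesion '{r.name}' below the "
                             f"{CONSTANTS.min_reliable_lesion_diameter:.0f} cm reliability limit")
        options.append(PlanOption(a, doses, ld, flags, suggested, notes))
    return options
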