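"""Lung shunt assessment.

Planar conjugate-view lung shunt fraction (LSF_planar), the three-class
workflow (no shunt / non-clinically-relevant / substantial), the LSF*
approximation used for liver quantification when no lung tomography is
acquired, tomographic LSF from the left-lung extrapolation, lung absorbed
dose, and the resin-sphere vendor prescription rule.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .constants import CONSTANTS
from .errors import InvalidInputError, UndefinedLSFError
from .voi import left_lung_total_counts  # noqa: F401  (re-exported: step 10 helper)


class PlanarView(str, enum.Enum):
    ANT = "ANT"
    POST = "POST"


class ShuntClass(str, enum.Enum):
    NONE = "NONE"
    NON_RELEVANT = "NON_RELEVANT"
    SUBSTANTIAL = "SUBSTANTIAL"


class LSFMode(str, enum.Enum):
    PLANAR_RAW = "PLANAR_RAW"
    STAR = "STAR"
    TOMO = "TOMO"


class LungCoverage(str, enum.Enum):
    WHOLE = "WHOLE"
    LEFT_LUNG = "LEFT_LUNG"
    TRUNCATED = "TRUNCATED"


@dataclass(frozen=True)
class PlanarRoiCounts:
    """Raw organ and background ROI counts for one planar view."""

    organ_raw: float
    organ_area: float
    bckg_counts: float
    bckg_area: float
    view: PlanarView = PlanarView.ANT

    def __post_init__(self):
        if self.organ_area <= 0 or self.bckg_area <= 0:
            raise InvalidInputError("ROI areas must be > 0")
        if self.organ_raw < 0 or self.bckg_counts < 0:
            raise InvalidInputError("ROI counts must be >= 0")
        object.__setattr__(self, "view", PlanarView(self.view))


def net_counts(roi: PlanarRoiCounts,
               bckg_factor: float = CONSTANTS.background_roi_factor) -> float:
    """Background-corrected organ counts.

    Subtracts the area-normalised background count density scaled by the
    large-organ correction factor (0.5); a negative result is clamped to
    zero with a warning.
    """
    net = roi.organ_raw - roi.bckg_counts / roi.bckg_area * roi.organ_area * bckg_factor
    if net < 0:
        warnings.warn(
            f"background-corrected counts negative ({net:.1f}); clamped to 0",
            stacklevel=2)
        return 0.0
    return net


def conjugate_mean(n_ant: float, n_post: float) -> float:
    """Geometric mean of net anterior and posterior counts."""
    if n_ant < 0 or n_post < 0:
        raise InvalidInputError("net counts must be >= 0")
    if n_ant == 0 or n_post == 0:
        if n_ant != n_post:
            warnings.warn("one conjugate view has zero net counts; geometric mean is 0",
                          stacklevel=2)
        return 0.0
    return math.sqrt(n_ant * n_post)


def lsf_planar(n_lung: float, n_liver: float) -> float:
    """Planar lung shunt fraction N_lung / (N_lung + N_liver)."""
    if n_lung < 0 or n_liver < 0:
        raise InvalidInputError("counts must be >= 0")
    total = n_lung + n_liver
    if total == 0:
        raise UndefinedLSFError("no counts in lung nor liver; LSF undefined")
    return n_lung / total


def lsf_tomo(n_lung_total: float, n_liver: float) -> float:
    """Tomographic LSF from whole-lung (left-lung extrapolated) and liver counts."""
    return lsf_planar(n_lung_total, n_liver)


def lsf_tomo_from_left_lung(left_counts: float, left_volume_ml: float,
                            total_volume_ml: float, n_liver: float,
                            coverage: LungCoverage | str = LungCoverage.LEFT_LUNG) -> float:
    """Tomographic LSF with the recommended left-lung count-density route.

    A direct whole-lung VOI is accepted but warned against (liver scatter
    inflates right-lung counts); a field of view covering only the lower
    lung is refused outright.
    """
    coverage = LungCoverage(coverage)
    if coverage is LungCoverage.TRUNCATED:
        raise InvalidInputError(
            "truncated-lung fields of view are refused: extrapolating from the "
            "lung base (most contaminated by liver scatter) overestimates LSF")
    if coverage is LungCoverage.WHOLE:
        warnings.warn(
            "whole-lung VOI counts are typically overestimated by liver scatter; "
            "the left-lung extrapolation is recommended", stacklevel=2)
        return lsf_tomo(left_counts, n_liver)
    return lsf_tomo(left_lung_total_counts(left_counts, left_volume_ml,
                                           total_volume_ml), n_liver)


def lsf_star(lsf_planar_value: float) -> float:
    """Approximate LSF for liver quantification: LSF_planar divided by 2.7.

    Planar imaging (no attenuation/scatter correction) systematically
    overestimates the tomographic shunt; the empirical average correction
    divisor is 2.7.
    """
    if not 0.0 <= lsf_planar_value < 1.0:
        raise InvalidInputError(f"LSF_planar must lie in [0, 1), got {lsf_planar_value}")
    return lsf_planar_value / CONSTANTS.lsf_planar_divisor


def classify_shunt(lsf_planar_value: float) -> ShuntClass:
    """Three-class shunt workflow: NONE / NON_RELEVANT / SUBSTANTIAL.

    The boundary value 0.10 is classed NON_RELEVANT because the substantial
    cut-off is a strict 'greater than'.
    """
    if not 0.0 <= lsf_planar_value < 1.0:
        raise InvalidInputError(f"LSF_planar must lie in [0, 1), got {lsf_planar_value}")
    if lsf_planar_value == 0.0:
        return ShuntClass.NONE
    if lsf_planar_value > CONSTANTS.lsf_substantial_cutoff:
        return ShuntClass.SUBSTANTIAL
    return ShuntClass.NON_RELEVANT


def lung_dose(a_total: float, lsf: float, lung_mass_kg: float = 1.0,
              dose_constant: float = CONSTANTS.dose_constant) -> float:
    """Lung absorbed dose (Gy) for a given administered activity and LSF.

    With the historical planar methodology the mass is the standard 1 kg;
    for tomographic assessments the individual CT-derived lung mass is used.
    """
    if lung_mass_kg <= 0:
        raise InvalidInputError("lung mass must be > 0")
    if a_total < 0:
        raise InvalidInputError("activity must be >= 0")
    if not 0.0 <= lsf < 1.0:
        raise InvalidInputError(f"LSF must lie in [0, 1), got {lsf}")
    return dose_constant * a_total / lung_mass_kg * lsf


def estimated_lung_counts(n_liver: float, lsf_star_value: float) -> float:
    """Starred lung counts N*_lungs = N_liver · LSF*/(1−LSF*).

    Inverts the LSF definition so a total-count denominator can be built
    when no lung tomography was acquired.
    """
    if not 0.0 <= lsf_star_value < 1.0:
        raise InvalidInputError(f"LSF* must lie in [0, 1), got {lsf_star_value}")
    if n_liver < 0:
        raise InvalidInputError("liver counts must be >= 0")
    return n_liver * lsf_star_value / (1.0 - lsf_star_value)


def liver_activity(a_total: float, lsf: float,
                   mode: LSFMode | str = LSFMode.TOMO) -> float:
    """Liver activity A_total · (1 − LSF); lung activity is A_total · LSF.

    ``mode`` records which LSF flavour was supplied (raw planar, starred
    approximation, or tomographic); the arithmetic is identical, the
    conservation A_liver + A_lung = A_total holds exactly in every mode.
    """
    LSFMode(mode)
    if not 0.0 <= lsf < 1.0:
        raise InvalidInputError(f"LSF must lie in [0, 1), got {lsf}")
    if a_total < 0:
        raise InvalidInputError("activity must be >= 0")
    return a_total * (1.0 - lsf)


def lung_activity(a_total: float, lsf: float) -> float:
    """Lung activity A_total · LSF."""
    if not 0.0 <= lsf < 1.0:
        raise InvalidInputError(f"LSF must lie in [0, 1), got {lsf}")
    return a_total * lsf


def resin_prescription_rule(lsf_planar_value: float) -> dict:
    """Resin-sphere vendor activity rule keyed on LSF_planar.

    Full activity up to LSF 0.10; 20 % reduction for 0.10 < LSF < 0.15;
    40 % reduction for 0.15 <= LSF < 0.20; contraindicated at LSF >= 0.20.
    The open band boundaries (0.15, 0.20) are assigned to the more
    conservative (lower-activity) option.
    """
    if not 0.0 <= lsf_planar_value < 1.0:
        raise InvalidInputError(f"LSF_planar must lie in [0, 1), got {lsf_planar_value}")
    if lsf_planar_value >= 0.20:
        return {"factor": 0.0, "contraindicated": True}
    if lsf_planar_value >= 0.15:
        return {"factor": 0.6, "contraindicated": False}
    if lsf_planar_value > CONSTANTS.lsf_substantial_cutoff:
        return {"factor": 0.8, "contraindicated": False}
    return {"factor": 1.0, "contraindicated": False}


@dataclass
class ShuntAssessment:
    """Bundle of shunt quantities feeding quantification and planning."""

    lsf_planar: float
    lsf_star: float
    shunt_class: ShuntClass
    lung_mass_kg: float
    lung_dose_gy: float
    lsf_tomo: float | None = None

    def __post_init__(self):
        self.shunt_class = ShuntClass(self.shunt_class)
        for nm in ("lsf_planar", "lsf_star"):
            v = getattr(self, nm)
            if not 0.0 <= v < 1.0:
                raise InvalidInputError(f"{nm} must lie in [0, 1), got {v}")
        if self.lsf_tomo is not None and not 0.0 <= self.lsf_tomo < 1.0:
            raise InvalidInputError(f"lsf_tomo must lie in [0, 1), got {self.lsf_tomo}")
        if self.lsf_planar > 0:
            expected = lsf_star(self.lsf_planar)
            if abs(self.lsf_star - expected) > 1e-9:
                raise InvalidInputError(
                    f"lsf_star {self.lsf_star} inconsistent with lsf_planar/"
                    f"{CONSTANTS.lsf_planar_divisor}")
        if self.shunt_class is not classify_shunt(self.lsf_planar):
            raise InvalidInputError("shunt_class inconsistent with lsf_planar cut-offs")

    @property
    def best_lsf(self) -> float:
        """LSF to use for liver quantification: tomographic if present, else LSF*."""
        return self.lsf_tomo if self.lsf_tomo is not None else self.lsf_star

    def to_json(self, path=None):
        payload = {"lsf_planar": self.lsf_planar, "lsf_star": self.lsf_star,
                   "lsf_tomo": self.lsf_tomo, "shunt_class": self.shunt_class.value,
                   "lung_mass_kg": self.lung_mass_kg, "lung_dose_gy": self.lung_dose_gy}
        if path is None:
            return json.dumps(payload, indent=2)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, source) -> "ShuntAssessment":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(payload["lsf_planar"], payload["lsf_star"],
                   ShuntClass(payload["shunt_class"]), payload["lung_mass_kg"],
                   payload["lung_dose_gy"], payload.get("lsf_tomo"))


def assess_from_planar(lung_rois, liver_rois, a_total: float,
                       lung_mass_kg: float = 1.0,
                       conjugate: bool = True,
                       lsf_tomo_value: float | None = None) -> ShuntAssessment:
    """Full planar workflow: background correction, conjugate mean, LSF, dose.

    ``lung_rois`` / ``liver_rois`` are one or two :class:`PlanarRoiCounts`
    (ANT only, or ANT+POST for the conjugate-view default).  With
    ``conjugate=False`` only the anterior view is used (the legacy
    single-view methodology the historical dose limits rest on).
    """
    def organ_net(rois) -> float:
        rois = [rois] if isinstance(rois, PlanarRoiCounts) else list(rois)
        by_view = {r.view: net_counts(r) for r in rois}
        if conjugate and len(by_view) == 2:
            return conjugate_mean(by_view[PlanarView.ANT], by_view[PlanarView.POST])
        if PlanarView.ANT not in by_view:
            raise InvalidInputError("an anterior view is required")
        return by_view[PlanarView.ANT]

    n_lung = organ_net(lung_rois)
    n_liver = organ_net(liver_rois)
    lsf_p = lsf_planar(n_lung, n_liver)
    return ShuntAssessment(
        lsf_planar=lsf_p, lsf_star=lsf_star(lsf_p), shunt_class=classify_shunt(lsf_p),
        lung_mass_kg=lung_mass_kg,
        lung_dose_gy=lung_dose(a_total, lsf_p, lung_mass_kg),
        lsf_tomo=lsf_tomo_value)


def read_planar_roi_csv(path) -> dict:
    """Read a planar ROI table into {organ: [PlanarRoiCounts, ...]}.

    Expected columns: view, organ, raw_counts, area_px, bckg_counts,
    bckg_area_px.
    """
    df = pd.read_csv(path)
    required = {"view", "organ", "raw_counts", "area_px", "bckg_counts", "bckg_area_px"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"planar ROI CSV missing columns: {sorted(missing)}")
    out: dict = {}
    for _, row in df.iterrows():
        roi = PlanarRoiCounts(row["raw_counts"], row["area_px"], row["bckg_counts"],
                              row["bckg_area_px"], PlanarView(str(row["view"]).upper()))
        out.setdefault(str(row["organ"]).lower(), []).append(roi)
    return out
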