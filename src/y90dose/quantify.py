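"""Patient-relative image quantification.

The conversion factor CF (GBq per image count) is the ratio of the known
90Y activity — intended activity before therapy, net administered activity
after — to the total image counts (liver plus lung).  Because every VOI
activity is CF times the VOI counts, the calibration is scale-free: any
global rescaling of image counts cancels out of all activities and doses.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass

from .constants import CONSTANTS
from .errors import InvalidInputError
from .grid import Session
from .shunt import estimated_lung_counts


class ActivityBasis(str, enum.Enum):
    INTENDED_ACTIVITY = "INTENDED_ACTIVITY"
    NET_ADMINISTERED = "NET_ADMINISTERED"


@dataclass(frozen=True)
class ConversionFactor:
    """Patient-relative calibration: GBq of 90Y per image count.

    ``approximate`` marks factors built from the starred lung-count estimate
    (pre-therapy only, when no lung tomography is available).
    """

    value: float
    basis: ActivityBasis = ActivityBasis.INTENDED_ACTIVITY
    session: Session = Session.PRE
    approximate: bool = False

    def __post_init__(self):
        object.__setattr__(self, "basis", ActivityBasis(self.basis))
        object.__setattr__(self, "session", Session(self.session))
        if not (self.value > 0 and math.isfinite(self.value)):
            raise InvalidInputError(f"conversion factor must be finite and > 0, got {self.value}")
        if self.approximate and self.session is not Session.PRE:
            raise InvalidInputError("an approximate (starred) CF is a pre-therapy construct")

    def __float__(self):
        return self.value


def conversion_factor(a_total: float, n_total: float,
                      basis: ActivityBasis | str = ActivityBasis.INTENDED_ACTIVITY,
                      session: Session | str = Session.PRE,
                      approximate: bool = False) -> ConversionFactor:
    """CF = A_total / N_total.

    ``n_total`` must be the total (liver + lung) image counts, measured or
    reconstructed via the starred estimate.
    """
    if a_total <= 0:
        raise InvalidInputError("total activity must be > 0")
    if n_total <= 0:
        raise InvalidInputError("total counts must be > 0")
    return ConversionFactor(a_total / n_total, basis, session, approximate)


def conversion_factor_star(a_total: float, n_liver: float, lsf_star_value: float,
                           basis: ActivityBasis | str = ActivityBasis.INTENDED_ACTIVITY,
                           ) -> ConversionFactor:
    """Approximate CF* from liver counts and LSF* when lungs were not imaged.

    Reconstructs N*_total = N_liver + N_liver · LSF*/(1 − LSF*) and divides.
    """
    if n_liver <= 0:
        raise InvalidInputError("liver counts must be > 0")
    n_total = n_liver + estimated_lung_counts(n_liver, lsf_star_value)
    return conversion_factor(a_total, n_total, basis, Session.PRE, approximate=True)


def activity_of_voi(cf: ConversionFactor | float, n_voi: float) -> float:
    """A_VOI = CF · N_VOI (GBq).

    Disjoint VOIs partitioning the total counts recover A_total exactly, by
    linearity.
    """
    if n_voi < 0:
        raise InvalidInputError("VOI counts must be >= 0")
    return float(cf) * n_voi


def net_injected_activity(shipped: float, residual: float) -> float:
    """Net injected activity: shipped minus residual (vial, tubing, catheter)."""
    if shipped < 0 or residual < 0:
        raise InvalidInputError("activities must be >= 0")
    if residual > shipped:
        raise InvalidInputError(
            f"residual activity ({residual} GBq) exceeds shipped ({shipped} GBq)")
    return shipped - residual


def pet_preset_activity(a_y90: float) -> float:
    """90Y activity scaled by the positron branching ratio.

    The value to enter in a PET console when acquiring 90Y with a long-lived
    positron emitter preset, so that the absolute calibration returns
    positron-equivalent activity.
    """
    if a_y90 < 0:
        raise InvalidInputError("activity must be >= 0")
    return a_y90 * CONSTANTS.positron_branching


def decay_factor(elapsed_h: float, half_life_h: float = CONSTANTS.half_life_phys) -> float:
    """exp(-ln2 · t / T): simple decay correction between reference times."""
    if half_life_h <= 0:
        raise InvalidInputError("half-life must be > 0")
    return math.exp(-math.log(2.0) * elapsed_h / half_life_h)


def activity_record_json(shipped: float, residual: float,
                         reference_time: str = "", injection_time: str = "",
                         path=None):
    """JSON record of the administered-activity bookkeeping."""
    payload = {"shipped_gbq": shipped, "residual_gbq": residual,
               "net_gbq": net_injected_activity(shipped, residual),
               "reference_time": reference_time, "injection_time": injection_time}
    if path is None:
        return json.dumps(payload, indent=2)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
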