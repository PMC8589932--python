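"""VOI algebra and the compartment segmentation sequence.

Implements Boolean mask operations, the adaptive NM isocontour whose volume
is matched to a CT volume, the two-VOI measurement convention (volume from
CT, counts from the nuclear-medicine image) and the full multi-compartment
segmentation bookkeeping, including the treated-volume fraction Vf and the
left-lung count extrapolation.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .constants import CONSTANTS
from .errors import (ConvergenceError, GridMismatchError, InconsistencyError,
                     InvalidInputError, ZeroVolumeError)
from .grid import CountImage, Mask, MaskSource


class BooleanOp(str, enum.Enum):
    UNION = "UNION"
    INTERSECT = "INTERSECT"
    SUBTRACT = "SUBTRACT"


class Role(str, enum.Enum):
    WHOLE_LIVER = "WHOLE_LIVER"
    NTL = "NTL"                      # non-tumoural whole liver
    PL = "PL"                        # perfused liver
    PNTL = "PNTL"                    # perfused non-tumoural liver
    LESION_CT = "LESION_CT"
    LESION_PERFUSED = "LESION_PERFUSED"
    NON_TARGET_LESIONS = "NON_TARGET_LESIONS"
    NECROSIS = "NECROSIS"
    LUNG = "LUNG"
    THROMBUS = "THROMBUS"


#: density (g/cm^3) used to convert a compartment volume to mass
ROLE_DENSITY = {role: CONSTANTS.density_soft_tissue for role in Role}
ROLE_DENSITY[Role.LUNG] = CONSTANTS.density_lung_nominal


def mask_combine(a: Mask, b: Mask, op: BooleanOp | str) -> Mask:
    """Voxelwise set operation between two masks on the same grid."""
    a.grid.require_same(b.grid, f"masks '{a.name}' and '{b.name}'")
    op = BooleanOp(op)
    if op is BooleanOp.UNION:
        data, sym = a.data | b.data, "|"
    elif op is BooleanOp.INTERSECT:
        data, sym = a.data & b.data, "&"
    else:
        data, sym = a.data & ~b.data, "-"
    return Mask(a.grid, data, name=f"({a.name}{sym}{b.name})", source=a.source)


def _largest_component(binary: np.ndarray) -> np.ndarray:
    """Largest 26-connected component of a binary array."""
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return binary
    sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def adaptive_threshold_voi(img: CountImage, ct_mask: Mask,
                           exclude: Mask | None = None,
                           dilate_mm: float = 15.0,
                           tol_voxels: int = 0,
                           max_iter: int = 60) -> Mask:
    """NM isocontour VOI whose volume matches the CT volume.

    Bisects on the threshold, expressed as a fraction of the local count
    maximum in a dilated neighbourhood of ``ct_mask``, until the volume of
    the largest 26-connected component of the isocontour matches the CT
    volume.  Ties are resolved toward the lower threshold (larger VOI),
    which is conservative for normal-tissue dose.  Voxels in ``exclude``
    (e.g. a known low-perfusion core) never enter the returned mask.
    """
    ct_mask.require_nonempty()
    img.grid.require_same(ct_mask.grid, "image and CT mask")
    if exclude is not None:
        img.grid.require_same(exclude.grid, "image and exclusion mask")

    # search neighbourhood: CT mask dilated by dilate_mm
    it = max(1, int(np.ceil(dilate_mm / min(img.grid.voxel_size_mm))))
    neigh = ndimage.binary_dilation(ct_mask.data, iterations=it)
    local = np.where(neigh, img.values, 0.0)
    if exclude is not None:
        local = np.where(exclude.data, 0.0, local)
    local_max = float(local.max())
    if local_max <= 0:
        raise ConvergenceError(
            "no positive counts near the CT mask; cannot place an isocontour")

    target = ct_mask.n_voxels

    def component_at(frac: float) -> np.ndarray:
        binary = local >= frac * local_max
        if not binary.any():
            return binary
        comp = _largest_component(binary)
        return comp

    lo, hi = 1e-6, 1.0          # low threshold -> big VOI, high -> small
    best = None
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        comp = component_at(mid)
        n = int(comp.sum())
        if best is None or abs(n - target) < abs(int(best[1].sum()) - target) or (
                abs(n - target) == abs(int(best[1].sum()) - target) and mid < best[0]):
            best = (mid, comp)
        if n == target:
            # tie-break toward lower threshold: keep shrinking hi
            hi = mid
        elif n > target:
            lo = mid
        else:
            hi = mid
    frac, comp = best
    n = int(comp.sum())
    if target > 0 and abs(n - target) > max(tol_voxels, 0.5 * target):
        raise ConvergenceError(
            f"isocontour volume ({n} voxels) not within +/-50% of CT volume "
            f"({target} voxels)")
    return Mask(img.grid, comp, name=f"{ct_mask.name}_nm_iso", source=MaskSource.NM)


@dataclass
class CompartmentMeasure:
    """Counts / volume / mass for one named compartment."""

    name: str
    role: Role
    counts: float
    volume_ml: float
    mass_kg: float

    def __post_init__(self):
        self.role = Role(self.role)
        if self.counts < -1e-9 or self.volume_ml < -1e-9:
            raise InvalidInputError(
                f"compartment '{self.name}': counts and volume must be >= 0")
        self.counts = max(float(self.counts), 0.0)
        self.volume_ml = max(float(self.volume_ml), 0.0)
        self.mass_kg = float(self.mass_kg)

    @classmethod
    def from_volume(cls, name, role, counts, volume_ml, density=None):
        role = Role(role)
        density = ROLE_DENSITY[role] if density is None else density
        return cls(name, role, counts, volume_ml, volume_ml * density * 1e-3)

    def equivalent_sphere_diameter_cm(self) -> float:
        return 2.0 * (3.0 * self.volume_ml / (4.0 * np.pi)) ** (1.0 / 3.0) if self.volume_ml else 0.0


def two_voi_measure(img: CountImage, nm_mask: Mask, ct_mask: Mask,
                    density: float = CONSTANTS.density_soft_tissue,
                    name: str | None = None,
                    role: Role = Role.LESION_CT) -> CompartmentMeasure:
    """Measure a compartment with counts from NM and volume from CT.

    This is the mismatch-robust convention: when the NM image is displaced
    (breathing) or blurred, the NM mask follows the counts while the CT mask
    keeps the anatomical volume.
    """
    img.grid.require_same(nm_mask.grid, "image and NM mask")
    img.grid.require_same(ct_mask.grid, "image and CT mask")
    ct_mask.require_nonempty()
    counts = img.counts_in(nm_mask)
    return CompartmentMeasure.from_volume(
        name or ct_mask.name, role, counts, ct_mask.volume_ml, density)


def left_lung_total_counts(left_counts: float, left_volume_ml: float,
                           total_volume_ml: float) -> float:
    """Whole-lung counts extrapolated from the left lung by volume proportion.

    The left lung is used because liver-scatter contamination inflates
    right-lung counts; the count density measured on the left is assumed
    representative of both lungs.
    """
    if left_volume_ml <= 0 or total_volume_ml <= 0:
        raise InvalidInputError("lung volumes must be > 0")
    if left_volume_ml > total_volume_ml + 1e-9:
        raise InvalidInputError("left lung volume exceeds total lung volume")
    if left_counts < 0:
        raise InvalidInputError("counts must be >= 0")
    return left_counts * total_volume_ml / left_volume_ml


def lung_mass_from_ct(lung_volume_ml: float,
                      density: float = CONSTANTS.density_lung_nominal) -> float:
    """Lung mass (kg) from CT volume at the nominal breathing-averaged density."""
    if lung_volume_ml <= 0:
        raise InvalidInputError("lung volume must be > 0")
    if density <= 0:
        raise InvalidInputError("density must be > 0")
    return lung_volume_ml * density * 1e-3


@dataclass
class SegmentationSet:
    """The measured compartment collection plus the treated-volume fraction."""

    compartments: list
    vf: float
    warnings_: list = field(default_factory=list)

    def __post_init__(self):
        if not -1e-12 <= self.vf <= 1 + 1e-12:
            raise InconsistencyError(f"Vf must lie in [0, 1], got {self.vf}")
        self.vf = float(min(max(self.vf, 0.0), 1.0))

    def get(self, key) -> CompartmentMeasure:
        """Look up a compartment by name, or by role if unique."""
        for c in self.compartments:
            if c.name == key:
                return c
        try:
            role = Role(key)
        except ValueError:
            raise KeyError(f"no compartment named '{key}'") from None
        matches = [c for c in self.compartments if c.role is role]
        if len(matches) != 1:
            raise KeyError(f"role {role.value} matches {len(matches)} compartments")
        return matches[0]

    def by_role(self, role: Role) -> list:
        role = Role(role)
        return [c for c in self.compartments if c.role is role]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"name": c.name, "role": c.role.value, "counts": c.counts,
              "volume_mL": c.volume_ml, "mass_kg": c.mass_kg}
             for c in self.compartments])

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path=None):
        payload = {"vf": self.vf, "warnings": list(self.warnings_),
                   "compartments": self.to_dataframe().to_dict(orient="records")}
        if path is None:
            return json.dumps(payload, indent=2)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, source) -> "SegmentationSet":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        comps = [CompartmentMeasure(c["name"], Role(c["role"]), c["counts"],
                                    c["volume_mL"], c["mass_kg"])
                 for c in payload["compartments"]]
        return cls(comps, payload["vf"], list(payload.get("warnings", [])))


def build_segmentation_set(img: CountImage,
                           voi_ct_whole_liver: Mask,
                           voi_ct_lesions=(),
                           voi_ct_non_target: Mask | None = None,
                           voi_ct_necrosis: Mask | None = None,
                           voi_nm_perfused_liver: Mask | None = None,
                           voi_nm_lesions=(),
                           voi_ct_lung: Mask | None = None,
                           voi_nm_lung: Mask | None = None,
                           liver_density: float = CONSTANTS.density_soft_tissue,
                           ) -> SegmentationSet:
    """Run the compartment measurement sequence.

    Lesion masks come in CT/NM pairs (``voi_ct_lesions[i]`` with
    ``voi_nm_lesions[i]``); with an empty lesion list the whole liver is
    treated as non-tumoural (the safe convention for infiltrative disease).
    When ``voi_nm_perfused_liver`` is omitted the CT liver doubles as the
    perfused-liver VOI (the simple well-matched situation).

    Bookkeeping (volumes from CT, counts from NM):

    * PL counts = image counts in the NM perfused-liver VOI; PL volume =
      (NM PL VOI intersected with the CT liver) minus necrosis.
    * PNTL counts = PL counts minus perfused-lesion counts minus necrosis
      counts; PNTL volume = PL volume minus CT lesion volumes.
    * NTL volume = whole liver minus CT lesions, non-target lesions and
      necrosis; NTL counts are the PNTL counts.
    * Vf = V(PNTL) / V(NTL).
    """
    voi_ct_lesions = list(voi_ct_lesions)
    voi_nm_lesions = list(voi_nm_lesions) if voi_nm_lesions else list(voi_ct_lesions)
    if len(voi_nm_lesions) != len(voi_ct_lesions):
        raise InvalidInputError("need one NM lesion mask per CT lesion mask")
    voi_ct_whole_liver.require_nonempty()
    if voi_nm_perfused_liver is None:
        voi_nm_perfused_liver = voi_ct_whole_liver

    grid = img.grid
    for m in [voi_ct_whole_liver, voi_nm_perfused_liver, voi_ct_non_target,
              voi_ct_necrosis, voi_ct_lung, voi_nm_lung, *voi_ct_lesions, *voi_nm_lesions]:
        if m is not None:
            grid.require_same(m.grid, "image and mask")

    vvol = grid.voxel_volume_ml
    warns: list = []

    necrosis_counts = img.counts_in(voi_ct_necrosis) if voi_ct_necrosis is not None else 0.0
    necrosis_vol = voi_ct_necrosis.volume_ml if voi_ct_necrosis is not None else 0.0
    non_target_vol = voi_ct_non_target.volume_ml if voi_ct_non_target is not None else 0.0
    non_target_counts = img.counts_in(voi_ct_non_target) if voi_ct_non_target is not None else 0.0

    # Perfused liver
    pl_counts = img.counts_in(voi_nm_perfused_liver)
    pl_in_liver = voi_nm_perfused_liver.data & voi_ct_whole_liver.data
    if voi_ct_necrosis is not None:
        pl_vol = float((pl_in_liver & ~voi_ct_necrosis.data).sum()) * vvol
    else:
        pl_vol = float(pl_in_liver.sum()) * vvol

    # Lesions: counts from NM masks, volume from CT masks
    lesions = []
    lesions_nm = []
    lesion_counts_sum = 0.0
    lesion_ct_vol_sum = 0.0
    for i, (mct, mnm) in enumerate(zip(voi_ct_lesions, voi_nm_lesions), start=1):
        mct.require_nonempty()
        counts = img.counts_in(mnm)
        lesion_counts_sum += counts
        lesion_ct_vol_sum += mct.volume_ml
        c = CompartmentMeasure.from_volume(
            mct.name or f"lesion_{i}", Role.LESION_CT, counts, mct.volume_ml,
            liver_density)
        if c.equivalent_sphere_diameter_cm() < CONSTANTS.min_reliable_lesion_diameter:
            msg = (f"lesion '{c.name}' CT-equivalent diameter "
                   f"{c.equivalent_sphere_diameter_cm():.2f} cm < "
                   f"{CONSTANTS.min_reliable_lesion_diameter} cm: partial-volume "
                   "effects dominate; exclude from analysis")
            warns.append(msg)
            warnings.warn(msg, stacklevel=2)
        lesions.append(c)
        lesions_nm.append(CompartmentMeasure.from_volume(
            f"{c.name}_perfused", Role.LESION_PERFUSED, counts, mnm.volume_ml,
            liver_density))

    if lesion_counts_sum - pl_counts > 1e-6 * max(pl_counts, 1.0):
        raise InconsistencyError(
            f"perfused-lesion counts ({lesion_counts_sum:.1f}) exceed perfused-liver "
            f"counts ({pl_counts:.1f})")

    pntl_counts = max(pl_counts - lesion_counts_sum - necrosis_counts, 0.0)
    pntl_vol = max(pl_vol - lesion_ct_vol_sum, 0.0)
    ntl_vol = max(voi_ct_whole_liver.volume_ml - lesion_ct_vol_sum
                  - non_target_vol - necrosis_vol, 0.0)
    if ntl_vol <= 0:
        raise InconsistencyError("non-tumoural liver volume is zero after subtraction")
    vf = min(pntl_vol / ntl_vol, 1.0)

    comps = [
        CompartmentMeasure.from_volume("whole_liver", Role.WHOLE_LIVER, pl_counts,
                                       voi_ct_whole_liver.volume_ml, liver_density),
        CompartmentMeasure.from_volume("perfused_liver", Role.PL, pl_counts,
                                       pl_vol, liver_density),
        *lesions, *lesions_nm,
        CompartmentMeasure.from_volume("pntl", Role.PNTL, pntl_counts, pntl_vol,
                                       liver_density),
        CompartmentMeasure.from_volume("ntl", Role.NTL, pntl_counts, ntl_vol,
                                       liver_density),
    ]
    if voi_ct_non_target is not None and non_target_vol > 0:
        comps.append(CompartmentMeasure.from_volume(
            "non_target_lesions", Role.NON_TARGET_LESIONS, non_target_counts,
            non_target_vol, liver_density))
    if voi_ct_necrosis is not None and necrosis_vol > 0:
        comps.append(CompartmentMeasure.from_volume(
            "necrosis", Role.NECROSIS, necrosis_counts, necrosis_vol, liver_density))
    if voi_ct_lung is not None:
        voi_ct_lung.require_nonempty()
        lung_counts = img.counts_in(voi_nm_lung if voi_nm_lung is not None else voi_ct_lung)
        comps.append(CompartmentMeasure.from_volume(
            "lung", Role.LUNG, lung_counts, voi_ct_lung.volume_ml))

    return SegmentationSet(comps, vf, warns)
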