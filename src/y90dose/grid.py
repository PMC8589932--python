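"""3D grid data model: images, masks and NIfTI I/O.

All algebra in the package assumes co-registered images sharing one grid;
the world-space affine is carried through I/O but never used in
computations.  Voxel membership in masks is binary (no partial-volume
weights) and volumes are voxel counts times the voxel volume.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GridMismatchError, InvalidInputError, ZeroVolumeError


class Modality(str, enum.Enum):
    TC99M_SPECT = "TC99M_SPECT"
    Y90_PET = "Y90_PET"
    PLANAR_SYNTH = "PLANAR_SYNTH"


class Session(str, enum.Enum):
    PRE = "PRE"
    POST = "POST"


class MaskSource(str, enum.Enum):
    CT = "CT"
    NM = "NM"


@dataclass(frozen=True)
class ImageGrid:
    """Voxel lattice shared by all images and masks of one case.

    ``frame_id`` is an opaque alignment tag: operations refuse to combine
    objects whose frames differ, which is the package's only registration
    "check" (images are assumed co-registered upstream).
    """

    shape: tuple
    voxel_size_mm: tuple
    frame_id: str = "default"

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm))
        if len(self.shape) != 3 or len(self.voxel_size_mm) != 3:
            raise InvalidInputError("ImageGrid is 3D: shape and voxel_size_mm need 3 entries")
        if any(s < 1 for s in self.shape):
            raise InvalidInputError(f"all grid dimensions must be >= 1, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise InvalidInputError(f"voxel sizes must be > 0, got {self.voxel_size_mm}")

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (= cm^3)."""
        return float(np.prod(self.voxel_size_mm)) / 1000.0

    @property
    def affine(self) -> np.ndarray:
        """Diagonal voxel-to-world affine (mm)."""
        a = np.diag(list(self.voxel_size_mm) + [1.0])
        return a

    def same_as(self, other: "ImageGrid") -> bool:
        return (self.shape == other.shape
                and self.voxel_size_mm == other.voxel_size_mm
                and self.frame_id == other.frame_id)

    def require_same(self, other: "ImageGrid", what: str = "objects"):
        if not self.same_as(other):
            raise GridMismatchError(
                f"{what} live on different grids: {self} vs {other}")


def _check_array(grid: ImageGrid, values: np.ndarray, what: str) -> np.ndarray:
    values = np.asarray(values)
    if values.shape != grid.shape:
        raise GridMismatchError(
            f"{what} shape {values.shape} does not match grid {grid.shape}")
    return values


@dataclass
class CountImage:
    """A 3D count image — the sole carrier of activity information."""

    grid: ImageGrid
    values: np.ndarray
    modality: Modality = Modality.TC99M_SPECT
    session: Session = Session.PRE

    def __post_init__(self):
        self.values = np.asarray(_check_array(self.grid, self.values, "image"), dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("count image contains non-finite values")
        if np.any(self.values < 0):
            raise InvalidInputError("count image contains negative values")
        self.modality = Modality(self.modality)
        self.session = Session(self.session)

    @property
    def total_counts(self) -> float:
        return float(self.values.sum())

    def counts_in(self, mask: "Mask") -> float:
        self.grid.require_same(mask.grid, "image and mask")
        return float(self.values[mask.data].sum())

    def shifted(self, shift_voxels, fill: float = 0.0) -> "CountImage":
        return replace(self, values=integer_shift(self.values, shift_voxels, fill))


@dataclass
class Mask:
    """A named boolean VOI on a grid."""

    grid: ImageGrid
    data: np.ndarray
    name: str = "mask"
    source: MaskSource = MaskSource.CT

    def __post_init__(self):
        self.data = np.asarray(_check_array(self.grid, self.data, f"mask '{self.name}'"),
                               dtype=bool)
        self.source = MaskSource(self.source)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_ml(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_ml

    @property
    def is_empty(self) -> bool:
        return self.n_voxels == 0

    def require_nonempty(self):
        if self.is_empty:
            raise ZeroVolumeError(f"mask '{self.name}' is empty")
        return self

    def equivalent_sphere_diameter_cm(self) -> float:
        """Diameter (cm) of the sphere with this VOI's volume."""
        if self.is_empty:
            return 0.0
        return 2.0 * (3.0 * self.volume_ml / (4.0 * np.pi)) ** (1.0 / 3.0)

    def shifted(self, shift_voxels, name: str | None = None) -> "Mask":
        out = integer_shift(self.data.astype(float), shift_voxels, 0.0) > 0.5
        return Mask(self.grid, out, name=name or f"{self.name}_shifted",
                    source=self.source)


def integer_shift(values: np.ndarray, shift_voxels, fill: float = 0.0) -> np.ndarray:
    """Rigid integer-voxel shift with zero (or ``fill``) padding, no wrap.

    ``shift_voxels`` may be a scalar (axial shift along the last axis) or a
    3-sequence of per-axis integer shifts.
    """
    values = np.asarray(values, dtype=float)
    if np.isscalar(shift_voxels):
        shift = (0, 0, int(shift_voxels))
    else:
        shift = tuple(int(s) for s in shift_voxels)
    if len(shift) != values.ndim:
        raise InvalidInputError("shift must have one entry per image axis")
    out = np.full_like(values, fill)
    src, dst = [], []
    for axis, s in enumerate(shift):
        n = values.shape[axis]
        if abs(s) >= n:
            return out
        if s >= 0:
            src.append(slice(0, n - s))
            dst.append(slice(s, n))
        else:
            src.append(slice(-s, n))
            dst.append(slice(0, n + s))
    out[tuple(dst)] = values[tuple(src)]
    return out


# ---------------------------------------------------------------------------
# NIfTI I/O (nibabel)

def save_nifti(path, obj, dtype=np.float32):
    """Write a CountImage, Mask or raw array to NIfTI."""
    import nibabel as nib

    if isinstance(obj, CountImage):
        data, grid = obj.values, obj.grid
    elif isinstance(obj, Mask):
        data, grid = obj.data.astype(np.uint8), obj.grid
        dtype = np.uint8
    else:
        raise InvalidInputError("save_nifti expects a CountImage or Mask")
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), grid.affine)
    img.header.set_zooms(grid.voxel_size_mm)
    nib.save(img, str(path))


def load_count_image(path, modality=Modality.TC99M_SPECT, session=Session.PRE,
                     frame_id: str = "default") -> CountImage:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    grid = ImageGrid(data.shape, img.header.get_zooms()[:3], frame_id=frame_id)
    return CountImage(grid, data, modality=modality, session=session)


def load_mask(path, name: str = "mask", source=MaskSource.CT,
              frame_id: str = "default") -> Mask:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata()) > 0.5
    grid = ImageGrid(data.shape, img.header.get_zooms()[:3], frame_id=frame_id)
    return Mask(grid, data, name=name, source=source)


def load_label_masks(path, labels: dict, frame_id: str = "default") -> dict:
    """Split an integer label image into named masks.

    ``labels`` maps name -> integer label value.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata()).round().astype(int)
    grid = ImageGrid(data.shape, img.header.get_zooms()[:3], frame_id=frame_id)
    return {name: Mask(grid, data == value, name=name)
            for name, value in labels.items()}
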