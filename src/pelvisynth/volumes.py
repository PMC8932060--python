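"""Core volumetric data model and IO.

Volumes are held as numpy arrays indexed ``[x, y, z]`` together with the
physical geometry (spacing/origin/direction) that maps voxel indices to
millimetre coordinates.  All volumes are reoriented to a single right-handed
LPS axis convention on load so that registration and patch indexing can
assume one convention.  NIfTI is the canonical on-disk format; DICOM image
series and DICOM RT Dose are import-only.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "Modality",
    "ImageVolume",
    "MaskVolume",
    "DoseGrid",
    "read_volume",
    "write_volume",
    "resample_to_reference",
]

#: default out-of-field fill values per modality
DEFAULT_FILL = {"CT": -1000.0, "MR": 0.0, "DOSE": 0.0, "LABEL": 0.0}

_ORTHO_TOL = 1e-6


class Modality(str, enum.Enum):
    CT = "CT"
    MR = "MR"
    DOSE = "DOSE"
    LABEL = "LABEL"


def _as_modality(m) -> Modality:
    return m if isinstance(m, Modality) else Modality(str(m).upper())


@dataclass
class ImageVolume:
    """A 3D scalar lattice with physical geometry.

    Parameters
    ----------
    voxels
        3D array indexed ``[x, y, z]``.  HU for CT, arbitrary units for MR,
        Gy for DOSE.
    spacing
        Voxel pitch in mm per axis, strictly positive.
    origin
        Physical (mm, LPS) coordinate of voxel (0, 0, 0).
    direction
        Orthonormal 3x3 matrix whose columns are the physical directions of
        the voxel axes.
    modality
        One of CT / MR / DOSE / LABEL.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))
    modality: Modality = Modality.CT

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = np.asarray(self.direction, dtype=np.float64).reshape(3, 3)
        self.modality = _as_modality(self.modality)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-5):
            raise ValueError("direction matrix is not orthonormal")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")

    # -- geometry helpers ----------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def same_geometry(self, other: "ImageVolume", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )

    def index_to_physical(self, index: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to physical mm points."""
        idx = np.atleast_2d(np.asarray(index, dtype=float))
        pts = (self.direction @ (idx * np.asarray(self.spacing)).T).T + np.asarray(self.origin)
        return pts if np.asarray(index).ndim > 1 else pts[0]

    def physical_to_index(self, point: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(point, dtype=float)) - np.asarray(self.origin)
        idx = (self.direction.T @ pts.T).T / np.asarray(self.spacing)
        return idx if np.asarray(point).ndim > 1 else idx[0]

    def with_voxels(self, voxels: np.ndarray, modality: Modality | None = None) -> "ImageVolume":
        """Copy of this volume with new voxel data on the same lattice."""
        return ImageVolume(
            voxels=np.asarray(voxels, dtype=np.float64),
            spacing=self.spacing,
            origin=self.origin,
            direction=self.direction.copy(),
            modality=self.modality if modality is None else modality,
        )

    def copy(self) -> "ImageVolume":
        return self.with_voxels(self.voxels.copy())


@dataclass
class MaskVolume:
    """A binary lattice sharing the ImageVolume geometry contract."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        arr = np.asarray(self.voxels)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be exactly 0 or 1")
        self.voxels = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = np.asarray(self.direction, dtype=np.float64).reshape(3, 3)
        # reuse the ImageVolume geometry invariants
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-5):
            raise ValueError("direction matrix is not orthonormal")

    @property
    def shape(self):
        return self.voxels.shape

    def as_image(self, modality: Modality = Modality.LABEL) -> ImageVolume:
        return ImageVolume(self.voxels.astype(float), self.spacing, self.origin,
                           self.direction.copy(), modality)

    def as_bool(self) -> np.ndarray:
        return self.voxels.astype(bool)

    def count(self) -> int:
        return int(self.voxels.sum())

    def volume_mm3(self) -> float:
        return self.count() * float(np.prod(self.spacing))

    def same_geometry(self, other, tol: float = 1e-6) -> bool:
        return ImageVolume.same_geometry(self, other, tol)  # type: ignore[arg-type]

    def with_voxels(self, voxels: np.ndarray) -> "MaskVolume":
        return MaskVolume(np.asarray(voxels), self.spacing, self.origin, self.direction.copy())


def mask_from_image(img: ImageVolume, threshold: float = 0.5) -> MaskVolume:
    return MaskVolume((img.voxels > threshold).astype(np.uint8), img.spacing,
                      img.origin, img.direction.copy())


@dataclass
class DoseGrid:
    """Dose in Gy on a grid, with an optional reference point for point-dose lookup."""

    image: ImageVolume
    reference_point: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.image.modality != Modality.DOSE:
            self.image = replace(self.image, modality=Modality.DOSE)
        if np.any(self.image.voxels < 0):
            raise ValueError("dose values must be non-negative")
        if self.reference_point is not None:
            self.reference_point = tuple(float(c) for c in self.reference_point)
            idx = self.image.physical_to_index(np.asarray(self.reference_point))
            shape = np.asarray(self.image.shape)
            if np.any(idx < -0.5) or np.any(idx > shape - 0.5):
                raise ValueError("reference_point lies outside the dose grid extent")

    def point_dose(self, point=None) -> float:
        """Trilinear dose at a physical point (defaults to the reference point)."""
        if point is None:
            point = self.reference_point
        if point is None:
            raise ValueError("no point given and no reference_point set")
        from scipy.ndimage import map_coordinates

        idx = self.image.physical_to_index(np.asarray(point, dtype=float))
        return float(map_coordinates(self.image.voxels, np.asarray(idx).reshape(3, 1),
                                     order=1, mode="nearest")[0])


# ---------------------------------------------------------------------------
# SimpleITK bridging
# ---------------------------------------------------------------------------

def to_sitk(vol: ImageVolume | MaskVolume) -> sitk.Image:
    """Convert to a SimpleITK image (which indexes arrays [z, y, x])."""
    arr = vol.voxels if isinstance(vol, ImageVolume) else vol.voxels.astype(np.float64)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(vol.spacing))
    img.SetOrigin(tuple(vol.origin))
    img.SetDirection(tuple(np.asarray(vol.direction).ravel()))
    return img


def from_sitk(img: sitk.Image, modality: Modality | str = Modality.CT) -> ImageVolume:
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(np.float64)
    return ImageVolume(
        voxels=arr,
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
        direction=np.asarray(img.GetDirection()).reshape(3, 3),
        modality=_as_modality(modality),
    )


def _canonical(img: sitk.Image) -> sitk.Image:
    """Reorient to the LPS axis convention (identity direction up to axis flips)."""
    return sitk.DICOMOrient(img, "LPS")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_volume(path, format: str = "nifti", modality: Modality | str | None = None) -> ImageVolume:
    """Read a volume from disk.

    Parameters
    ----------
    path
        File path (NIfTI / RT Dose) or directory (DICOM series).
    format
        One of ``nifti``, ``dicom_series``, ``dicom_rtdose``.
    modality
        Modality tag for the returned volume; inferred as CT when omitted
        (DOSE for ``dicom_rtdose``).
    """
    path = Path(path)
    if format == "nifti":
        if not path.exists():
            raise FileNotFoundError(path)
        img = sitk.ReadImage(os.fspath(path), sitk.sitkFloat64)
        img = _canonical(img)
        return from_sitk(img, modality or Modality.CT)
    if format == "dicom_series":
        return _read_dicom_series(path, modality or Modality.CT)
    if format == "dicom_rtdose":
        return _read_rtdose(path)
    raise ValueError(f"unknown format {format!r}")


def _read_dicom_series(directory: Path, modality) -> ImageVolume:
    if not directory.is_dir():
        raise FileNotFoundError(directory)
    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(os.fspath(directory))
    if not files:
        raise ValueError(f"no DICOM series found in {directory}")
    _check_slice_spacing(files)
    reader.SetFileNames(files)
    img = sitk.Cast(reader.Execute(), sitk.sitkFloat64)
    return from_sitk(_canonical(img), modality)


def _check_slice_spacing(files, tol: float = 1e-3) -> None:
    import pydicom

    zs = []
    for f in files:
        ds = pydicom.dcmread(f, stop_before_pixels=True)
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is None:
            return
        zs.append(float(ipp[2]))
    zs = sorted(zs)
    gaps = np.diff(zs)
    if len(gaps) >= 2 and (gaps.max() - gaps.min()) > tol:
        raise ValueError(
            f"inconsistent slice spacing in DICOM series: gaps range "
            f"{gaps.min():.3f}-{gaps.max():.3f} mm"
        )


def _read_rtdose(path: Path) -> ImageVolume:
    import pydicom

    if not path.exists():
        raise FileNotFoundError(path)
    ds = pydicom.dcmread(os.fspath(path))
    if getattr(ds, "Modality", "") != "RTDOSE":
        raise ValueError(f"{path} is not a DICOM RT Dose file")
    scaling = float(ds.DoseGridScaling)
    arr = ds.pixel_array.astype(np.float64) * scaling  # (frames, rows, cols)
    spacing_xy = [float(v) for v in ds.PixelSpacing]  # (row, col) mm
    offsets = [float(v) for v in ds.GridFrameOffsetVector]
    dz = np.diff(offsets)
    if len(dz) and (dz.max() - dz.min()) > 1e-3:
        raise ValueError("non-uniform GridFrameOffsetVector in RT Dose")
    spacing = (spacing_xy[1], spacing_xy[0], float(dz[0]) if len(dz) else 1.0)
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    iop = [float(v) for v in getattr(ds, "ImageOrientationPatient",
                                     [1, 0, 0, 0, 1, 0])]
    row, col = np.asarray(iop[:3]), np.asarray(iop[3:])
    normal = np.cross(row, col)
    direction = np.column_stack([row, col, normal])
    vol = ImageVolume(arr.transpose(2, 1, 0), spacing, origin, direction, Modality.DOSE)
    return from_sitk(_canonical(to_sitk(vol)), Modality.DOSE)


def write_volume(volume: ImageVolume | MaskVolume, path) -> Path:
    """Write a volume as NIfTI; geometry round-trips through :func:`read_volume`."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory {path.parent} does not exist")
    img = to_sitk(volume)
    sitk.WriteImage(img, os.fspath(path))
    return path


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

_INTERP = {"nearest": sitk.sitkNearestNeighbor, "linear": sitk.sitkLinear}


def resample_to_reference(
    moving: ImageVolume,
    reference: ImageVolume | MaskVolume,
    interpolation: str = "linear",
    fill_value: float | None = None,
) -> ImageVolume:
    """Resample ``moving`` onto the lattice of ``reference``.

    Values are sampled from ``moving`` at the physical points of the
    reference lattice; points outside ``moving`` receive ``fill_value``
    (modality default when omitted).
    """
    if interpolation not in _INTERP:
        raise ValueError(f"interpolation must be one of {sorted(_INTERP)}")
    if fill_value is None:
        fill_value = DEFAULT_FILL[moving.modality.value]
    ref_img = to_sitk(reference if isinstance(reference, ImageVolume) else reference.as_image())
    out = sitk.Resample(
        to_sitk(moving), ref_img, sitk.Transform(),
        _INTERP[interpolation], float(fill_value), sitk.sitkFloat64,
    )
    return from_sitk(out, moving.modality)
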