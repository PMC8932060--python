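"""Preprocessing: bias-field correction, background masking, body-mask
extraction, bowel-gas override, HU-to-electron-density conversion.

Conventions follow standard radiotherapy practice: CT background is masked
to -1000 HU, MRI background to 0, and bowel gas (whose position is not
reproducible between scans) is overridden to the average HU of surrounding
tissue before dose comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volumes import ImageVolume, MaskVolume, Modality

__all__ = [
    "HUCurve",
    "correct_bias_field",
    "mask_background",
    "compute_body_mask",
    "override_gas",
    "hu_to_density",
    "DEFAULT_HU_CURVE",
]


@dataclass
class HUCurve:
    """Piecewise-linear HU -> relative electron density calibration.

    Control points must be strictly increasing in HU with non-negative
    densities; inputs outside the range clamp to the end densities.
    """

    control_points: list[tuple[float, float]]

    def __post_init__(self):
        if len(self.control_points) < 2:
            raise ValueError("HUCurve needs at least 2 control points")
        hu = np.asarray([p[0] for p in self.control_points], dtype=float)
        dens = np.asarray([p[1] for p in self.control_points], dtype=float)
        if np.any(np.diff(hu) <= 0):
            raise ValueError("HU values must be strictly increasing")
        if np.any(dens < 0):
            raise ValueError("densities must be non-negative")
        self._hu, self._dens = hu, dens

    def __call__(self, values: np.ndarray) -> np.ndarray:
        return np.interp(values, self._hu, self._dens)  # np.interp clamps at ends

    @classmethod
    def from_file(cls, path) -> "HUCurve":
        """Read a two-column plain-text table (HU density per line, '#' comments)."""
        pts = []
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            hu, dens = line.split()[:2]
            pts.append((float(hu), float(dens)))
        return cls(pts)


# air / lung / water / muscle / dense bone
DEFAULT_HU_CURVE = HUCurve([(-1000.0, 0.0), (-700.0, 0.3), (0.0, 1.0),
                            (40.0, 1.04), (1500.0, 1.85)])


def correct_bias_field(
    mri: ImageVolume,
    body_mask: MaskVolume,
    order: int = 2,
    method: str = "n4",
) -> ImageVolume:
    """Remove a smooth multiplicative intensity field from an MRI.

    The default estimator is the N4 algorithm (SimpleITK), which separates
    the smooth field from genuine tissue contrast.  ``method="polynomial"``
    fits a low-order polynomial to log intensities inside the mask instead;
    it is cheaper but can absorb anatomy on strongly structured images.
    The background is set to 0 and the mean intensity inside the mask is
    preserved.
    """
    if mri.modality != Modality.MR:
        raise ValueError("correct_bias_field expects an MR volume")
    if not mri.same_geometry(body_mask):
        raise ValueError("mask geometry differs from image geometry")
    inside = body_mask.as_bool()
    if not inside.any():
        raise ValueError("empty body mask: misconfigured pipeline")

    if method == "n4":
        corrected = _n4(mri, body_mask)
    elif method == "polynomial":
        corrected = _polyfit_bias(mri, inside, order)
    else:
        raise ValueError(f"unknown bias method {method!r}")

    out = corrected.copy()
    # preserve mean intensity inside the mask, background exactly 0
    mean_in, mean_out = mri.voxels[inside].mean(), out[inside].mean()
    if mean_out > 0:
        out[inside] *= mean_in / mean_out
    out[~inside] = 0.0
    return mri.with_voxels(out)


def _polyfit_bias(mri: ImageVolume, inside: np.ndarray, order: int) -> np.ndarray:
    vals = mri.voxels
    positive = inside & (vals > 0)
    if not positive.any():
        raise ValueError("no positive intensities inside mask")
    logv = np.log(vals[positive])
    coords = np.argwhere(positive).astype(float)
    # normalize coordinates to [-1, 1] for conditioning
    shape = np.asarray(vals.shape, dtype=float)
    coords = 2.0 * coords / (shape - 1) - 1.0

    cols = [np.ones(len(coords))]
    for d in range(1, order + 1):
        for i in range(3):
            cols.append(coords[:, i] ** d)
        if d >= 2:
            cols.append(coords[:, 0] * coords[:, 1])
            cols.append(coords[:, 0] * coords[:, 2])
            cols.append(coords[:, 1] * coords[:, 2])
    A = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(A, logv, rcond=None)

    all_idx = np.argwhere(np.ones_like(vals, dtype=bool)).astype(float)
    all_idx = 2.0 * all_idx / (shape - 1) - 1.0
    cols = [np.ones(len(all_idx))]
    for d in range(1, order + 1):
        for i in range(3):
            cols.append(all_idx[:, i] ** d)
        if d >= 2:
            cols.append(all_idx[:, 0] * all_idx[:, 1])
            cols.append(all_idx[:, 0] * all_idx[:, 2])
            cols.append(all_idx[:, 1] * all_idx[:, 2])
    field = (np.column_stack(cols) @ coef).reshape(vals.shape)
    # the fitted log-field includes the mean tissue level; dividing by its
    # exponential removes the smooth variation (mean rescaled by caller)
    field = np.exp(field - field[inside].mean())
    field = np.clip(field, 1e-3, None)
    return vals / field


def _n4(mri: ImageVolume, body_mask: MaskVolume) -> np.ndarray:
    import SimpleITK as sitk

    from .volumes import to_sitk

    img = sitk.Cast(to_sitk(mri), sitk.sitkFloat32)
    msk = sitk.Cast(to_sitk(body_mask.as_image()), sitk.sitkUInt8)
    shrunk = sitk.Shrink(img, [2, 2, 2])
    shrunk_msk = sitk.Shrink(msk, [2, 2, 2])
    n4 = sitk.N4BiasFieldCorrectionImageFilter()
    n4.Execute(shrunk, shrunk_msk)
    logfield = n4.GetLogBiasFieldAsImage(img)
    field = np.exp(sitk.GetArrayFromImage(logfield).transpose(2, 1, 0))
    return mri.voxels / np.clip(field, 1e-3, None)


def mask_background(image: ImageVolume, body_mask: MaskVolume, fill: float) -> ImageVolume:
    """Set voxels outside the body mask to ``fill``; inside voxels unchanged."""
    if not image.same_geometry(body_mask):
        raise ValueError("mask geometry differs from image geometry")
    out = image.voxels.copy()
    out[~body_mask.as_bool()] = fill
    return image.with_voxels(out)


def compute_body_mask(
    image: ImageVolume,
    threshold: float = -250.0,
    min_component_voxels: int = 100,
) -> MaskVolume:
    """Threshold-based body contour: largest connected component above
    ``threshold``, holes filled slice-wise (so internal gas stays inside)."""
    fg = image.voxels > threshold
    if not fg.any():
        raise ValueError(f"no voxel above threshold {threshold}")
    labels, n = ndimage.label(fg)
    if n == 0:
        raise ValueError("no connected component found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    if sizes[keep - 1] < min_component_voxels:
        raise ValueError("largest component smaller than min_component_voxels")
    body = labels == keep
    filled = np.zeros_like(body)
    for k in range(body.shape[2]):  # axial slices
        filled[:, :, k] = ndimage.binary_fill_holes(body[:, :, k])
    return MaskVolume(filled.astype(np.uint8), image.spacing, image.origin,
                      image.direction.copy())


def override_gas(
    ct: ImageVolume,
    body_mask: MaskVolume,
    gas_threshold: float = -300.0,
    neighborhood_mm: float = 10.0,
) -> ImageVolume:
    """Replace internal gas with the mean HU of surrounding tissue.

    Voxels inside the body below ``gas_threshold`` are treated as bowel gas
    and set to the mean of non-gas tissue within ``neighborhood_mm``.
    """
    if not ct.same_geometry(body_mask):
        raise ValueError("mask geometry differs from image geometry")
    body = body_mask.as_bool()
    gas = body & (ct.voxels < gas_threshold)
    if not gas.any():
        return ct.copy()

    tissue = body & ~gas
    footprint = _ball_footprint(neighborhood_mm, ct.spacing)
    tissue_f = tissue.astype(np.float64)
    num = ndimage.convolve(ct.voxels * tissue_f, footprint, mode="constant", cval=0.0)
    den = ndimage.convolve(tissue_f, footprint, mode="constant", cval=0.0)
    starved = gas & (den < 0.5)
    if starved.any():
        raise ValueError(
            f"{int(starved.sum())} gas voxels have no non-gas tissue within "
            f"{neighborhood_mm} mm"
        )
    out = ct.voxels.copy()
    out[gas] = num[gas] / den[gas]
    return ct.with_voxels(out)


def _ball_footprint(radius_mm: float, spacing) -> np.ndarray:
    r = [max(1, int(np.floor(radius_mm / s))) for s in spacing]
    grids = np.meshgrid(*[np.arange(-n, n + 1) * s for n, s in zip(r, spacing)],
                        indexing="ij")
    dist2 = sum(g**2 for g in grids)
    return (dist2 <= radius_mm**2).astype(np.float64)


def hu_to_density(ct: ImageVolume, curve: HUCurve | None = None) -> ImageVolume:
    """Apply a piecewise-linear HU-to-relative-electron-density calibration."""
    if curve is None:
        curve = DEFAULT_HU_CURVE
    return ct.with_voxels(curve(ct.voxels))
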