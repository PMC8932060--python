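"""Registration chains for atlas construction and sCT synthesis.

Two chains are provided:

* ``register_structure_guided`` — aligns an atlas CT to its own MRI using
  signed distance maps of the combined bone+bladder labels: a 6-DoF rigid
  stage (mean-squared-error metric on the distance maps), a fast
  symmetric-forces demons stage on the same distance maps (smoothing
  standard deviation 1), and a final multiscale deformable refinement of
  the CT to the MRI driven by a mutual-information metric on the
  intensities.

* ``register_mri_pair`` — aligns an atlas MRI to a target MRI: a 6-DoF
  rigid stage driven by the body masks (distance-map MSE restricted to the
  masks), then diffeomorphic demons on the intensities (smoothing standard
  deviation 3, 3 multi-resolution levels).

Transform convention: a :class:`TransformChain` maps *fixed-space* physical
points into *moving-space* points (the resampling convention), and its
stages are listed in point-application order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import SimpleITK as sitk

from .volumes import ImageVolume, MaskVolume, Modality, from_sitk, to_sitk

__all__ = [
    "TransformStage",
    "TransformChain",
    "RegistrationReport",
    "RegistrationSettings",
    "signed_distance",
    "register_structure_guided",
    "register_mri_pair",
    "apply_transform",
]


@dataclass
class TransformStage:
    """One stage of a chain: either 6 rigid parameters (3 rotations rad,
    3 translations mm, plus the rotation centre) or a dense displacement
    field in mm on the fixed geometry."""

    kind: Literal["rigid", "displacement_field"]
    rigid_params: tuple[float, ...] | None = None  # (rx, ry, rz, tx, ty, tz)
    rigid_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    field: sitk.Image | None = None  # sitkVectorFloat64 displacement, mm

    def to_sitk(self) -> sitk.Transform:
        if self.kind == "rigid":
            t = sitk.Euler3DTransform()
            t.SetCenter(self.rigid_center)
            t.SetParameters(tuple(float(p) for p in self.rigid_params))
            return t
        return sitk.DisplacementFieldTransform(sitk.Image(self.field))

    def max_displacement(self) -> float:
        if self.kind == "rigid":
            return float(np.linalg.norm(self.rigid_params[3:]))
        arr = sitk.GetArrayFromImage(self.field)
        return float(np.sqrt((arr**2).sum(axis=-1)).max())


@dataclass
class TransformChain:
    """Ordered stages mapping fixed-space points to moving-space points."""

    stages: list[TransformStage] = field(default_factory=list)

    def to_sitk(self) -> sitk.Transform:
        if not self.stages:
            return sitk.Transform(3, sitk.sitkIdentity)
        comp = sitk.CompositeTransform(3)
        # SimpleITK applies the most recently added transform first, so add
        # in reverse of the point-application order.
        for stage in reversed(self.stages):
            comp.AddTransform(stage.to_sitk())
        return comp

    def transform_point(self, point) -> tuple[float, float, float]:
        return self.to_sitk().TransformPoint(tuple(float(c) for c in point))


@dataclass
class RegistrationReport:
    final_metric_value: float
    iterations_run: list[int]
    converged: list[bool]


@dataclass
class RegistrationSettings:
    """Iteration caps, smoothing sigmas and sanity bounds for both chains."""

    rigid_iterations: int = 100
    rigid_learning_rate: float = 2.0
    demons_iterations_per_level: tuple[int, ...] = (50, 50, 50)
    structure_demons_sigma: float = 1.0  # fast symmetric forces stage
    mri_demons_sigma: float = 3.0  # diffeomorphic demons stage
    mri_demons_levels: int = 3
    demons_max_rms: float = 5e-4  # plateau stop for the demons filters
    distance_clamp_mm: float = 20.0  # far-field clamp for rigid distance MSE
    distance_band_mm: float = 12.0  # metric support: |distance| below this band
    distance_pad_voxels: int = 12  # moving-map padding (domain under transforms)
    bspline_grid_spacing_mm: float = 60.0
    bspline_iterations: int = 25
    refine_with_bspline: bool = True
    max_displacement_mm: float = 60.0  # divergence sanity bound
    histogram_match: bool = True


# ---------------------------------------------------------------------------
# distance maps
# ---------------------------------------------------------------------------

def signed_distance(mask: MaskVolume) -> ImageVolume:
    """Euclidean signed distance in mm: negative inside, positive outside,
    magnitude below one voxel pitch adjacent to the boundary."""
    from scipy.ndimage import distance_transform_edt

    n_on = mask.count()
    if n_on == 0:
        raise ValueError("empty mask has no signed distance map")
    if n_on == int(np.prod(mask.shape)):
        raise ValueError("full mask has no boundary")
    inside = mask.as_bool()
    d_in = distance_transform_edt(inside, sampling=mask.spacing)
    d_out = distance_transform_edt(~inside, sampling=mask.spacing)
    sd = d_out - d_in
    return mask.as_image().with_voxels(sd)


# ---------------------------------------------------------------------------
# rigid stage
# ---------------------------------------------------------------------------

def _mask_centroid_mm(mask: MaskVolume) -> np.ndarray:
    from scipy.ndimage import center_of_mass

    idx = np.asarray(center_of_mass(mask.voxels), dtype=float)
    return np.asarray(mask.as_image().index_to_physical(idx), dtype=float)


def _clamped_distance(mask: MaskVolume, clamp_mm: float,
                      pad_voxels: int = 0) -> sitk.Image:
    """Signed distance map clamped so the far field is bounded; keeps the
    rigid MSE basin centred on the structures instead of flat background.

    ``pad_voxels`` extends the domain with the clamp value so that metric
    samples of a moving image stay in-domain under candidate transforms
    (out-of-domain samples are silently dropped by the metric, which lets a
    sliding transform fake a good score on the shrinking overlap)."""
    dm = signed_distance(mask)
    img = to_sitk(dm.with_voxels(np.clip(dm.voxels, -clamp_mm, clamp_mm)))
    if pad_voxels:
        img = sitk.ConstantPad(img, [pad_voxels] * 3, [pad_voxels] * 3,
                               float(clamp_mm))
    return img


def _fixed_distance_and_band(mask: MaskVolume, settings: "RegistrationSettings"):
    """Clamped fixed distance map plus the metric-support band around the
    structure boundary (|distance| < band); sampling away from the boundary
    carries no alignment information and invites flat-background matches."""
    dm = signed_distance(mask)
    band = (np.abs(dm.voxels) < settings.distance_band_mm).astype(np.uint8)
    clamped = to_sitk(dm.with_voxels(
        np.clip(dm.voxels, -settings.distance_clamp_mm,
                settings.distance_clamp_mm)))
    band_img = sitk.GetImageFromArray(band.transpose(2, 1, 0))
    band_img.CopyInformation(clamped)
    return clamped, band_img


def _rigid_register(
    fixed: sitk.Image,
    moving: sitk.Image,
    settings: RegistrationSettings,
    fixed_centroid: np.ndarray | None = None,
    moving_centroid: np.ndarray | None = None,
    fixed_mask: sitk.Image | None = None,
):
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetMetricSamplingStrategy(reg.REGULAR)
    reg.SetMetricSamplingPercentage(0.25, seed=12345)
    if fixed_mask is not None:
        # restrict sampling to the structure neighbourhood; a moving mask is
        # deliberately NOT set (shrinking overlap can fake a good metric)
        reg.SetMetricFixedMask(fixed_mask)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=settings.rigid_learning_rate,
        minStep=1e-4,
        numberOfIterations=settings.rigid_iterations,
        relaxationFactor=0.6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    init = sitk.Euler3DTransform()
    if fixed_centroid is not None and moving_centroid is not None:
        # moments initialization: translation aligning the mask centroids
        init.SetCenter(tuple(float(c) for c in fixed_centroid))
        init.SetTranslation(tuple(float(c) for c in
                                  np.asarray(moving_centroid) - fixed_centroid))
    else:
        init = sitk.Euler3DTransform(sitk.CenteredTransformInitializer(
            fixed, moving, sitk.Euler3DTransform(),
            sitk.CenteredTransformInitializerFilter.GEOMETRY))
    reg.SetInitialTransform(init, inPlace=True)
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    out = reg.Execute(sitk.Cast(fixed, sitk.sitkFloat64),
                      sitk.Cast(moving, sitk.sitkFloat64))
    euler = sitk.Euler3DTransform(out)
    stage = TransformStage(
        kind="rigid",
        rigid_params=tuple(euler.GetParameters()),
        rigid_center=tuple(euler.GetCenter()),
    )
    iters = max(1, reg.GetOptimizerIteration())
    converged = reg.GetOptimizerStopConditionDescription().find("Maximum") < 0
    return stage, float(reg.GetMetricValue()), iters, converged


# ---------------------------------------------------------------------------
# demons stages
# ---------------------------------------------------------------------------

def _demons_multires(
    fixed: sitk.Image,
    moving: sitk.Image,
    filter_factory,
    sigma: float,
    levels: int,
    iters_per_level,
    max_rms: float,
):
    """Run a demons filter through a shrink pyramid, upsampling the field
    between levels.  Returns (displacement field image, iterations, converged)."""
    fixed = sitk.Cast(fixed, sitk.sitkFloat32)
    moving = sitk.Cast(moving, sitk.sitkFloat32)
    shrinks = [2 ** (levels - 1 - i) for i in range(levels)]
    field = None
    total_iters = 0
    converged = True
    for level, shrink in enumerate(shrinks):
        if shrink > 1:
            f_lvl = sitk.Shrink(fixed, [shrink] * 3)
            m_lvl = sitk.Shrink(moving, [shrink] * 3)
        else:
            f_lvl, m_lvl = fixed, moving
        dem = filter_factory()
        iters = iters_per_level[min(level, len(iters_per_level) - 1)]
        dem.SetNumberOfIterations(int(iters))
        dem.SetSmoothDisplacementField(True)
        dem.SetStandardDeviations(float(sigma))
        dem.SetMaximumRMSError(max_rms)
        if field is not None:
            field = sitk.Resample(field, f_lvl, sitk.Transform(),
                                  sitk.sitkLinear, 0.0, sitk.sitkVectorFloat64)
            field = dem.Execute(f_lvl, m_lvl, field)
        else:
            field = dem.Execute(f_lvl, m_lvl)
        total_iters += max(1, dem.GetElapsedIterations())
        converged = converged and (dem.GetElapsedIterations() < iters
                                   or dem.GetRMSChange() < max_rms * 10)
    field = sitk.Resample(field, fixed, sitk.Transform(),
                          sitk.sitkLinear, 0.0, sitk.sitkVectorFloat64)
    return sitk.Cast(field, sitk.sitkVectorFloat64), total_iters, converged


def _check_sane(stage: TransformStage, settings: RegistrationSettings) -> None:
    d = stage.max_displacement()
    if d > settings.max_displacement_mm:
        raise RuntimeError(
            f"divergent registration: max displacement {d:.1f} mm exceeds "
            f"sanity bound {settings.max_displacement_mm} mm"
        )


# ---------------------------------------------------------------------------
# chain 1: structure-guided CT -> MRI (atlas construction)
# ---------------------------------------------------------------------------

def register_structure_guided(
    fixed_mri_labels: MaskVolume,
    moving_ct_labels: MaskVolume,
    fixed_mri: ImageVolume,
    moving_ct: ImageVolume,
    settings: RegistrationSettings | None = None,
) -> tuple[TransformChain, RegistrationReport]:
    """Structure-guided CT-to-MRI alignment for atlas construction.

    The labels are the combined bone+bladder binaries of each modality; the
    rigid and demons stages act on their signed distance maps, and a final
    multiscale deformable stage refines the alignment on the intensity
    images with a mutual-information metric.
    """
    settings = settings or RegistrationSettings()
    dm_fixed, fmask = _fixed_distance_and_band(fixed_mri_labels, settings)
    dm_moving = _clamped_distance(moving_ct_labels, settings.distance_clamp_mm,
                                  pad_voxels=settings.distance_pad_voxels)

    rigid, metric, it_r, conv_r = _rigid_register(
        dm_fixed, dm_moving, settings,
        fixed_centroid=_mask_centroid_mm(fixed_mri_labels),
        moving_centroid=_mask_centroid_mm(moving_ct_labels),
        fixed_mask=fmask)
    _check_sane(rigid, settings)

    # demons on the distance maps, after applying the rigid stage
    moved_dm = sitk.Resample(dm_moving, dm_fixed, rigid.to_sitk(),
                             sitk.sitkLinear, 0.0, sitk.sitkFloat64)
    fld, it_d, conv_d = _demons_multires(
        dm_fixed, moved_dm,
        sitk.FastSymmetricForcesDemonsRegistrationFilter,
        sigma=settings.structure_demons_sigma, levels=1,
        iters_per_level=settings.demons_iterations_per_level,
        max_rms=settings.demons_max_rms,
    )
    demons_stage = TransformStage(kind="displacement_field", field=fld)
    _check_sane(demons_stage, settings)

    stages = [demons_stage, rigid]
    iters = [it_r, it_d]
    conv = [conv_r, conv_d]

    if settings.refine_with_bspline:
        partial = TransformChain(stages=list(stages))
        warped_ct = apply_transform(moving_ct, partial, fixed_mri,
                                    interpolation="linear", fill_value=-1000.0)
        bspline, it_b, conv_b = _bspline_refine(
            to_sitk(fixed_mri), to_sitk(warped_ct), settings)
        _check_sane(bspline, settings)
        full = TransformChain(stages=[bspline, demons_stage, rigid])
        # structure-guided acceptance: keep the intensity refinement only if
        # it does not degrade the label alignment the chain is built around
        from .validation import dice as _dice

        d_partial = _dice(warp_mask(moving_ct_labels, partial, fixed_mri_labels),
                          fixed_mri_labels)
        d_full = _dice(warp_mask(moving_ct_labels, full, fixed_mri_labels),
                       fixed_mri_labels)
        if d_full >= d_partial - 1e-6:
            stages = full.stages
            iters.append(it_b)
            conv.append(conv_b)

    chain = TransformChain(stages=stages)
    report = RegistrationReport(final_metric_value=metric,
                                iterations_run=iters, converged=conv)
    return chain, report


def _bspline_refine(fixed: sitk.Image, moving: sitk.Image,
                    settings: RegistrationSettings):
    """Multiscale free-form (B-spline) refinement with a mutual-information
    metric; the refinement field is converted to a dense displacement field."""
    fixed = sitk.Cast(fixed, sitk.sitkFloat32)
    moving = sitk.Cast(moving, sitk.sitkFloat32)
    size_mm = [sz * sp for sz, sp in zip(fixed.GetSize(), fixed.GetSpacing())]
    mesh = [max(2, int(round(s / settings.bspline_grid_spacing_mm))) for s in size_mm]
    tx = sitk.BSplineTransformInitializer(fixed, mesh)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    reg.SetMetricSamplingStrategy(reg.REGULAR)
    reg.SetMetricSamplingPercentage(0.2, seed=12345)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsLBFGSB(numberOfIterations=settings.bspline_iterations)
    reg.SetInitialTransform(tx, inPlace=True)
    reg.SetShrinkFactorsPerLevel([2, 1])
    reg.SetSmoothingSigmasPerLevel([1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    out = reg.Execute(fixed, moving)
    field = sitk.TransformToDisplacementField(
        out, sitk.sitkVectorFloat64, fixed.GetSize(),
        fixed.GetOrigin(), fixed.GetSpacing(), fixed.GetDirection())
    stage = TransformStage(kind="displacement_field", field=field)
    iters = max(1, reg.GetOptimizerIteration())
    return stage, iters, True


# ---------------------------------------------------------------------------
# chain 2: target MRI -> atlas MRI (sCT synthesis)
# ---------------------------------------------------------------------------

def register_mri_pair(
    target_mri: ImageVolume,
    target_body: MaskVolume,
    atlas_mri: ImageVolume,
    atlas_body: MaskVolume,
    settings: RegistrationSettings | None = None,
) -> tuple[TransformChain, RegistrationReport]:
    """Body-mask rigid then diffeomorphic demons, mapping target -> atlas."""
    settings = settings or RegistrationSettings()
    dm_fixed, fmask = _fixed_distance_and_band(target_body, settings)
    dm_moving = _clamped_distance(atlas_body, settings.distance_clamp_mm,
                                  pad_voxels=settings.distance_pad_voxels)

    rigid, metric, it_r, conv_r = _rigid_register(
        dm_fixed, dm_moving, settings,
        fixed_centroid=_mask_centroid_mm(target_body),
        moving_centroid=_mask_centroid_mm(atlas_body),
        fixed_mask=fmask)
    _check_sane(rigid, settings)

    fixed_img = to_sitk(target_mri)
    moving_img = sitk.Resample(to_sitk(atlas_mri), fixed_img, rigid.to_sitk(),
                               sitk.sitkLinear, 0.0, sitk.sitkFloat64)
    if settings.histogram_match:
        # inter-subject MR intensity scales are arbitrary; match before demons
        moving_img = sitk.HistogramMatching(
            moving_img, fixed_img, numberOfHistogramLevels=128,
            numberOfMatchPoints=7, thresholdAtMeanIntensity=True)

    fld, it_d, conv_d = _demons_multires(
        fixed_img, moving_img,
        sitk.DiffeomorphicDemonsRegistrationFilter,
        sigma=settings.mri_demons_sigma, levels=settings.mri_demons_levels,
        iters_per_level=settings.demons_iterations_per_level,
        max_rms=settings.demons_max_rms,
    )
    demons_stage = TransformStage(kind="displacement_field", field=fld)
    _check_sane(demons_stage, settings)

    chain = TransformChain(stages=[demons_stage, rigid])
    report = RegistrationReport(final_metric_value=metric,
                                iterations_run=[it_r, it_d],
                                converged=[conv_r, conv_d])
    return chain, report


# ---------------------------------------------------------------------------
# application
# ---------------------------------------------------------------------------

_INTERP = {"nearest": sitk.sitkNearestNeighbor, "linear": sitk.sitkLinear}


def apply_transform(
    moving: ImageVolume,
    chain: TransformChain,
    reference: ImageVolume | MaskVolume,
    interpolation: str = "linear",
    fill_value: float | None = None,
) -> ImageVolume:
    """Warp ``moving`` onto the reference lattice through the chain.

    Each reference voxel's physical point is mapped through all stages in
    order and sampled from ``moving``; use linear interpolation for
    intensities and nearest for labels.
    """
    from .volumes import DEFAULT_FILL

    if interpolation not in _INTERP:
        raise ValueError(f"interpolation must be one of {sorted(_INTERP)}")
    if fill_value is None:
        fill_value = DEFAULT_FILL[moving.modality.value]
    ref = reference if isinstance(reference, ImageVolume) else reference.as_image()
    out = sitk.Resample(to_sitk(moving), to_sitk(ref), chain.to_sitk(),
                        _INTERP[interpolation], float(fill_value), sitk.sitkFloat64)
    return from_sitk(out, moving.modality)


def warp_mask(mask: MaskVolume, chain: TransformChain,
              reference: ImageVolume | MaskVolume) -> MaskVolume:
    warped = apply_transform(mask.as_image(), chain, reference,
                             interpolation="nearest", fill_value=0.0)
    return MaskVolume((warped.voxels > 0.5).astype(np.uint8), warped.spacing,
                      warped.origin, warped.direction.copy())
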