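"""Procedural paired CT/MRI pelvic phantoms.

Each phantom case is an elliptical body cross-section containing a spinal
column, a pelvic ring, two femoral heads, a bladder, and optional bowel-gas
pockets.  CT voxels are drawn per tissue class from Gaussian HU
distributions; the MRI maps the same classes through a deliberately
*non-monotone* intensity table (bone is bright on CT but dark on MR), then
applies a smooth multiplicative bias field and additive noise.  Because no
global intensity mapping links MR to CT, atlas fusion has to exploit spatial
correspondence — which is what makes the phantom a meaningful test bed.

Inter-subject variation is affine (scaling/translation of the primitives)
plus a smooth radial perturbation of the body outline, so deformable
registration has real work to do but remains solvable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volumes import DoseGrid, ImageVolume, MaskVolume, Modality

__all__ = [
    "PhantomParams",
    "AtlasCase",
    "Atlas",
    "generate_phantom_case",
    "generate_cohort",
    "generate_synthetic_dose",
]

# textbook HU means; the sd column keeps tissue texture plausible
DEFAULT_TISSUE_HU = {
    "air": (-1000.0, 10.0),
    "fat": (-100.0, 20.0),
    "muscle": (40.0, 15.0),
    "bladder": (15.0, 10.0),
    "bone": (700.0, 50.0),
}

# non-monotone in HU by construction: bone is dark on MR, fat/bladder bright
DEFAULT_MRI_MEAN = {
    "air": 0.0,
    "fat": 800.0,
    "muscle": 400.0,
    "bladder": 900.0,
    "bone": 150.0,
}


@dataclass
class PhantomParams:
    """Generation parameters for a phantom cohort.

    Ranges are (min, max) in mm; anatomy parameters are drawn uniformly from
    them per case.  ``grid_shape`` must be at least 16 per axis and
    ``tissue_hu`` must cover air/fat/muscle/bone/bladder.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 60)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    body_axes_range: tuple[tuple[float, float], tuple[float, float]] = ((70.0, 84.0), (52.0, 62.0))
    bone_radius_range: tuple[float, float] = (10.0, 14.0)
    bladder_axes_range: tuple[float, float] = (18.0, 26.0)
    gas_pocket_count_range: tuple[int, int] = (1, 3)
    gas_pocket_radius_range: tuple[float, float] = (4.0, 8.0)
    tissue_hu: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_HU))
    mri_mapping: dict = field(default_factory=lambda: dict(DEFAULT_MRI_MEAN))
    bias_amplitude: float = 0.2
    noise_sd: float = 10.0
    sex: str = "female"
    seed: int = 0

    def __post_init__(self):
        if any(n < 16 for n in self.grid_shape):
            raise ValueError("grid_shape must be >= 16 per axis")
        for lo, hi in (*self.body_axes_range, self.bone_radius_range,
                       self.bladder_axes_range, self.gas_pocket_count_range):
            if lo > hi:
                raise ValueError("all ranges must satisfy min <= max")
        missing = set(DEFAULT_TISSUE_HU) - set(self.tissue_hu)
        if missing:
            raise ValueError(f"tissue_hu missing classes: {sorted(missing)}")


@dataclass
class AtlasCase:
    """A paired, co-registered CT+MRI with ground-truth masks."""

    case_id: str
    mri: ImageVolume
    ct: ImageVolume
    bone_mask: MaskVolume
    bladder_mask: MaskVolume
    body_mask: MaskVolume
    sex: str = "female"

    def __post_init__(self):
        geoms = [self.ct, self.bone_mask, self.bladder_mask, self.body_mask]
        if not all(self.mri.same_geometry(g) for g in geoms):
            raise ValueError("all five volumes of an AtlasCase must share one geometry")

    def validate_backgrounds(self) -> None:
        outside = ~self.body_mask.as_bool()
        if not np.all(self.ct.voxels[outside] == -1000):
            raise ValueError("CT background must be exactly -1000")
        if not np.all(self.mri.voxels[outside] == 0):
            raise ValueError("MRI background must be exactly 0")


@dataclass
class Atlas:
    """A sex-tagged ordered collection of atlas cases."""

    cases: list[AtlasCase]
    sex: str = "female"

    def __post_init__(self):
        if len(self.cases) < 1:
            raise ValueError("atlas needs at least one case")
        ids = [c.case_id for c in self.cases]
        if len(set(ids)) != len(ids):
            raise ValueError("case_ids must be unique")
        if any(c.sex != self.sex for c in self.cases):
            raise ValueError("all cases must share the atlas sex tag")

    def __len__(self):
        return len(self.cases)

    def __iter__(self):
        return iter(self.cases)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _grids_mm(shape, spacing):
    """Physical coordinate grids centred on the volume, mm."""
    axes = [(np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _sphere(x, y, z, center, radius):
    return (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2 <= radius**2


def _ellipsoid(x, y, z, center, axes):
    return (
        ((x - center[0]) / axes[0]) ** 2
        + ((y - center[1]) / axes[1]) ** 2
        + ((z - center[2]) / axes[2]) ** 2
        <= 1.0
    )


def generate_phantom_case(params: PhantomParams, case_seed: int) -> AtlasCase:
    """Generate one paired CT/MRI case; pure function of (params, case_seed)."""
    rng = np.random.default_rng(case_seed)
    shape, spacing = params.grid_shape, params.spacing
    x, y, z = _grids_mm(shape, spacing)
    z_extent = (shape[2] - 1) * spacing[2]

    # --- body: perturbed ellipse, constant profile along z -------------
    ax = rng.uniform(*params.body_axes_range[0])
    ay = rng.uniform(*params.body_axes_range[1])
    theta = np.arctan2(y / ay, x / ax)
    # smooth radial perturbation of the outline (low angular order)
    c2, c3 = rng.uniform(-0.05, 0.05, size=2)
    phase2, phase3 = rng.uniform(0, 2 * np.pi, size=2)
    pert = 1.0 + c2 * np.cos(2 * theta + phase2) + c3 * np.cos(3 * theta + phase3)
    # superior-inferior profile: linear taper plus a waist/hip bulge, so the
    # outline varies along z as real bodies do (and axial alignment stays
    # well-posed for registration)
    zh = z_extent / 2.0
    taper_c = rng.choice([-1.0, 1.0]) * rng.uniform(0.08, 0.15)
    bulge_c = rng.choice([-1.0, 1.0]) * rng.uniform(0.06, 0.12)
    bulge_z0 = rng.uniform(-0.3, 0.3) * zh
    taper = 1.0 + taper_c * (z / zh) + bulge_c * (((z - bulge_z0) / zh) ** 2 - 0.5)
    # smooth end caps well inside the grid: the body closes superiorly and
    # inferiorly instead of being cut by the volume edge, and stays fully in
    # the field of view under modest rigid perturbations
    caps = np.sqrt(np.clip(1.0 - (z / (0.85 * zh)) ** 8, 0.0, None))
    body = ((x / ax) ** 2 + (y / ay) ** 2) <= (pert * taper * caps) ** 2

    # --- bone primitives ----------------------------------------------
    r_bone = rng.uniform(*params.bone_radius_range)
    jit = lambda s: rng.uniform(-s, s)  # noqa: E731 - positional jitter, mm
    hip_y = 0.10 * ay + jit(3.0)
    hip_z = -0.25 * z_extent / 2
    femoral_l = _sphere(x, y, z, (-0.62 * ax + jit(3.0), hip_y, hip_z), r_bone)
    femoral_r = _sphere(x, y, z, (+0.62 * ax + jit(3.0), hip_y, hip_z), r_bone)
    # spine: posterior cylinder along z
    spine_r = 0.9 * r_bone
    spine = ((x - jit(2.0)) ** 2 + (y - (0.55 * ay + jit(2.0))) ** 2) <= spine_r**2
    # pelvic ring: elliptic annulus over the middle slices
    ring_ax, ring_ay = 0.55 * ax, 0.55 * ay
    ring_rho = np.sqrt((x / ring_ax) ** 2 + (y / ring_ay) ** 2)
    ring_halfwidth = 0.5 * r_bone / min(ring_ax, ring_ay)
    ring = (np.abs(ring_rho - 1.0) <= ring_halfwidth) & (np.abs(z - hip_z / 2) <= 0.22 * z_extent)
    bone = (femoral_l | femoral_r | spine | ring) & body

    # --- bladder -------------------------------------------------------
    bl = rng.uniform(*params.bladder_axes_range)
    bl_center = (jit(4.0), -0.35 * ay + jit(3.0), 0.05 * z_extent / 2 + jit(4.0))
    bladder = _ellipsoid(x, y, z, bl_center, (bl, 0.8 * bl, 0.9 * bl)) & body & ~bone
    if not bladder.any():
        raise ValueError("sampled bladder does not fit inside the body")
    if not bone.any():
        raise ValueError("sampled bone primitives do not fit inside the body")

    # --- tissue class map ---------------------------------------------
    # subcutaneous fat shell: interior of a shrunk body outline is muscle
    inner = ((x / (0.85 * ax)) ** 2 + (y / (0.85 * ay)) ** 2) <= (pert * taper * caps) ** 2
    classes = np.zeros(shape, dtype=np.uint8)  # 0=air
    order = {"air": 0, "fat": 1, "muscle": 2, "bladder": 3, "bone": 4, "gas": 5}
    classes[body] = order["fat"]
    classes[body & inner] = order["muscle"]
    classes[bladder] = order["bladder"]
    classes[bone] = order["bone"]

    # --- gas pockets: inside body, clear of bone and bladder -----------
    n_gas = int(rng.integers(params.gas_pocket_count_range[0],
                             params.gas_pocket_count_range[1] + 1))
    gas = np.zeros(shape, dtype=bool)
    for _ in range(n_gas):
        for _attempt in range(50):
            r_gas = rng.uniform(*params.gas_pocket_radius_range)
            center = (rng.uniform(-0.4 * ax, 0.4 * ax),
                      rng.uniform(-0.1 * ay, 0.35 * ay),
                      rng.uniform(-0.2, 0.2) * z_extent)
            pocket = _sphere(x, y, z, center, r_gas)
            if pocket.any() and not (pocket & (bone | bladder | ~body)).any():
                gas |= pocket
                break
    classes[gas] = order["gas"]

    # --- CT ------------------------------------------------------------
    ct_vals = np.full(shape, -1000.0)
    class_names = {order["fat"]: "fat", order["muscle"]: "muscle",
                   order["bladder"]: "bladder", order["bone"]: "bone"}
    for code, name in class_names.items():
        sel = classes == code
        mu, sd = params.tissue_hu[name]
        ct_vals[sel] = mu + sd * rng.standard_normal(int(sel.sum()))
    sel = classes == order["gas"]
    mu, sd = params.tissue_hu["air"]
    ct_vals[sel] = mu + sd * rng.standard_normal(int(sel.sum()))
    ct_vals[~body] = -1000.0

    # --- MRI -----------------------------------------------------------
    mri_vals = np.zeros(shape)
    mri_names = dict(class_names)
    for code, name in mri_names.items():
        mri_vals[classes == code] = params.mri_mapping[name]
    mri_vals[classes == order["gas"]] = params.mri_mapping["air"]
    if params.bias_amplitude > 0:
        bias = _bias_field(shape, spacing, params.bias_amplitude, rng)
        mri_vals = mri_vals * bias
    if params.noise_sd > 0:
        mri_vals = mri_vals + params.noise_sd * rng.standard_normal(shape)
    mri_vals = np.clip(mri_vals, 0.0, None)
    mri_vals[~body] = 0.0

    geom = dict(spacing=spacing, origin=(0.0, 0.0, 0.0), direction=np.eye(3))
    return AtlasCase(
        case_id=f"case_{case_seed:08d}",
        mri=ImageVolume(mri_vals, modality=Modality.MR, **geom),
        ct=ImageVolume(ct_vals, modality=Modality.CT, **geom),
        bone_mask=MaskVolume(bone.astype(np.uint8), **geom),
        bladder_mask=MaskVolume(bladder.astype(np.uint8), **geom),
        body_mask=MaskVolume(body.astype(np.uint8), **geom),
        sex=params.sex,
    )


def _bias_field(shape, spacing, amplitude, rng):
    """Smooth multiplicative field: 1 + amplitude * broad Gaussian bump."""
    x, y, z = _grids_mm(shape, spacing)
    extent = [(n - 1) * s for n, s in zip(shape, spacing)]
    center = [rng.uniform(-0.3, 0.3) * e for e in extent]
    sigma = [rng.uniform(0.4, 0.7) * e for e in extent]
    bump = np.exp(-(((x - center[0]) / sigma[0]) ** 2
                    + ((y - center[1]) / sigma[1]) ** 2
                    + ((z - center[2]) / sigma[2]) ** 2))
    sign = rng.choice([-1.0, 1.0])
    return 1.0 + sign * amplitude * bump


def generate_cohort(params: PhantomParams, n: int, seed: int | None = None) -> Atlas:
    """Generate an ``n``-case cohort with per-case seeds derived from ``seed``."""
    if n < 2:
        raise ValueError("a cohort needs n >= 2 cases")
    if seed is None:
        seed = params.seed
    ss = np.random.SeedSequence(seed)
    case_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]
    cases = [generate_phantom_case(params, cs) for cs in case_seeds]
    return Atlas(cases=cases, sex=params.sex)


def generate_synthetic_dose(
    reference: ImageVolume,
    target_center: tuple[float, float, float],
    target_radius: float,
    prescription: float,
    penumbra_sigma: float,
) -> DoseGrid:
    """A spherical target dose: flat prescription inside the target, Gaussian
    penumbra of width ``penumbra_sigma`` outside."""
    if prescription <= 0 or target_radius <= 0:
        raise ValueError("prescription and target_radius must be positive")
    center = np.asarray(target_center, dtype=float)
    idx = reference.physical_to_index(center)
    shape = np.asarray(reference.shape)
    if np.any(idx < 0) or np.any(idx > shape - 1):
        raise ValueError("target_center lies outside the reference extent")

    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in reference.shape], indexing="ij")
    pts = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
    phys = reference.index_to_physical(pts)
    dist = np.linalg.norm(phys - center, axis=1).reshape(reference.shape)
    excess = np.clip(dist - target_radius, 0.0, None)
    dose = prescription * np.exp(-(excess**2) / (2.0 * penumbra_sigma**2))
    img = reference.with_voxels(dose, modality=Modality.DOSE)
    return DoseGrid(image=img, reference_point=tuple(center))
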