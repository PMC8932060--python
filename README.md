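# pelvisynth

Multi-atlas synthetic-CT (sCT) generation and dosimetric validation for
pelvic MRI-only radiotherapy planning.

## The problem

Radiotherapy dose calculation needs electron densities, which come from CT
Hounsfield units (HU). MRI has far better soft-tissue contrast but its
intensities carry no density information, so MRI-only planning requires a
*synthetic CT*: an HU volume estimated from the patient's MRI. A clinically
proven route is the hybrid multi-atlas approach: a library ("atlas") of
co-registered CT+MRI pairs is deformably registered to the new patient's
MRI, each atlas CT is propagated through the same deformation, and the
propagated HU values are fused per voxel by **local weighted voting**:

    w_i(v) = (d_i(v) + eps)^(-g)
    sCT(v) = sum_i w_i(v) CT_i(v) / sum_i w_i(v)

where `d_i(v)` is the mean squared intensity difference between the patch
(radius 2 voxels, i.e. 5x5x5) of the target MRI and of registered atlas MRI
`i` around voxel `v`, and `g` is a gain (default 1) that sharpens the vote
toward locally similar atlases. Registration is two-stage: a 6-DoF rigid
alignment driven by body masks (mean-squared error on signed distance
maps), then diffeomorphic demons on intensities (smoothing sigma 3, 3
multi-resolution levels). Atlas construction itself uses structure-guided
registration on the combined bone+bladder labels (rigid + fast
symmetric-forces demons on distance maps, multiscale deformable refinement
with a mutual-information metric).

The validation suite mirrors clinical sCT QA: mean error and mean absolute
error in HU (body, bone and soft tissue, with the superior/inferior 3 cm
excluded), Dice overlap and volume differences of body and bone contours,
cumulative DVH curves and parameters (D_x, V_d, Dmean), percentage dose
difference `(D_sCT - D_CT)/D_CT x 100` at a reference point, an exact
Wilcoxon signed-rank test, and a 3D gamma index with configurable
dose/distance criteria (3%/2 mm, 2%/2 mm, 1%/1 mm), a 15 mm body-perimeter
erosion and a 10% low-dose threshold.

Because paired patient data cannot be redistributed, the package ships a
procedural pelvic phantom: paired CT/MRI volumes with body, bone, bladder
and bowel-gas structures, inter-subject shape variation, a smooth MRI bias
field and noise. The MRI-to-CT intensity mapping is deliberately
non-monotone (bone is bright on CT, dark on MR), so fusion cannot succeed
by any global intensity mapping — it must exploit registered spatial
correspondence, exactly like the clinical problem.

## Worked example

Run a leave-one-out experiment on a 3-case phantom cohort (each case's sCT
is synthesized from the other two and compared with its true CT):

```bash
pelvisynth loo --n 3 --seed 17 --out demo/
```

which prints the aggregate table (mean and one standard deviation over the
cohort; about 80 s on one CPU):

```
metric                                  mean          sd
body_dsc                               0.973       0.007
body_mae_hu                           74.434      15.713
body_me_hu                           -18.758      35.294
bone_dsc                               0.889       0.042
bone_mae_hu                          104.311      55.246
gamma_1pct_1mm_pass_pct               98.953       0.906
gamma_2pct_2mm_pass_pct               99.930       0.119
gamma_3pct_2mm_pass_pct               99.958       0.074
icru_point_dose_diff_pct               0.080       0.412
...
```

Reading the numbers: the synthesized CTs agree with the ground-truth CTs to
a mean absolute error of ~74 HU over the body; bone segmented from the sCT
at +200 HU overlaps the true bone mask with Dice 0.89; and when a synthetic
treatment dose is perturbed by the sCT-vs-CT electron density differences,
99.96% of evaluated voxels pass the clinical 3%/2 mm gamma criterion with a
reference-point dose deviation well under 1%.

The same workflow is available from Python:

```python
from pelvisynth import PhantomParams, generate_cohort, PipelineConfig, run_leave_one_out

atlas = generate_cohort(PhantomParams(seed=17), n=6, seed=17)
manifest = run_leave_one_out(atlas, PipelineConfig(seed=17))
print(manifest.aggregate["body_mae_hu"])
```

Other commands: `pelvisynth phantom` (write a cohort as NIfTI + manifest),
`preprocess` (N4 bias correction, background masking), `register` (either
registration chain, writing the warped image and transform chain),
`synthesize` (sCT for a target MRI from an atlas manifest) and `validate`
(HU error / Dice / gamma report for a CT-sCT pair).

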