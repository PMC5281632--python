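# patchsr — patch-based super-resolution of MRSI metabolite maps

Magnetic resonance spectroscopic imaging (MRSI) quantifies metabolite
concentrations — N-acetylaspartate, myo-inositol, and others — but at voxel
sizes around 1 cm³, far coarser than anatomical MRI. `patchsr` upsamples a
quantified low-resolution metabolite map onto a finer grid by borrowing
spatial structure from co-registered high-resolution anatomy (T1-weighted and
FLAIR volumes plus soft GM/WM/CSF segmentations), while staying consistent
with the measured data. It is aimed at neuroimaging researchers working with
metabolite maps in conditions such as multiple sclerosis (MS), where lesion
versus normal-appearing-white-matter contrast matters.

## Method

Let `y` be the measured low-resolution map and `x` the unknown
high-resolution map with `y = H(x)`, where `H` is a point-spread-function
(PSF) blur followed by block averaging. Starting from a linear upsampling of
`y` (scale factor 2 per axis by default), the algorithm alternates:

**Reconstruction.** Every voxel is replaced by a convex combination of the
voxels in its search volume ζᵢ (an 11³ cube by default):

```
E(xᵢ | ζᵢ) = Σⱼ [(1 − α(xᵢ)) · w_MRI(xᵢ,xⱼ) + α(xᵢ) · w_MRSI(xᵢ,xⱼ)] · xⱼ
```

`w_MRSI` are non-local-means weights from 8³ patches of the metabolite map
itself, `w_MRSI ∝ exp(−‖N̂ᵢ−N̂ⱼ‖² / (2N hᵢ²))`, with the noise scale `hᵢ`
estimated from pseudo-residuals against the 6-neighborhood mean. `w_MRI`
uses patches of the anatomical channels and additionally gates each
candidate by shared tissue membership, `w_MRI ∝ (1/K) Σₖ pᵢₖ pⱼₖ ·
exp(−‖N̂ᵢ−N̂ⱼ‖² / (2N hᵢ²))`. The blending weight α is 1 inside lesions
(metabolite-driven, since anatomy under-represents metabolic abnormality
there) and 0 elsewhere.

**Mean correction.** The estimate is convolved with a separable sinc PSF
(the PSF of phase-encoded MRSI), block-averaged to the acquisition grid, and
the residual against `y` is added back to every voxel of the block:
`x̂ᵢ = xᵢ + (yₚ − H(x)ₚ)`. With the PSF disabled this makes every block mean
match the data exactly.

Iteration stops when the relative change ‖xᵗ − xᵗ⁻¹‖/‖xᵗ⁻¹‖ drops below
1e-3 (typically 4–5 iterations).

The package also provides the conventional upsamplers used as baselines
(nearest-neighbor, trilinear, cubic B-spline), two procedural phantoms with
an acquisition simulator (noise → zero-phase anti-alias filter →
decimation), and the evaluation statistics: global SSIM with zero stability
constants, Welch's t-test, Cohen's d, ROI median/IQR summaries.

## Worked example

```python
import patchsr as ps

# simulated MS brain: NAA = 30 (GM), 25 (WM), 20 (lesions) a.u.,
# Gaussian noise sigma 2, anti-alias filtering, x2 decimation
out = ps.run_brain_experiment(seed=0)
print(out["report"][["method", "nwm_median", "lesion_median",
                     "effect_size", "ssim"]].to_string(index=False))
```

prints (seed 0):

```
 method  nwm_median  lesion_median  effect_size     ssim
   pbsr   24.752308      20.568538     5.164336 0.994754
     nn   24.792965      20.338651     3.214204 0.968720
 linear   24.679752      20.943764     3.822264 0.983025
bspline   24.776444      20.367419     4.083510 0.992324
```

`nwm_median` is the median reconstructed NAA in white matter surrounding the
lesions (truth 25) and `lesion_median` inside lesions (truth 20); all
methods land close to both. The patch-based method separates the two
compartments most cleanly — the largest lesion-vs-WM effect size (Cohen's
d 5.16) and the highest structural similarity to the noiseless ground truth
(SSIM 0.995).

The same from the command line:

```sh
patchsr experiment --experiment brain --seed 0 --outdir results/brain
patchsr experiment --experiment cylinder --seed 0 --outdir results/cylinder
patchsr upsample --method pbsr --input naa_lr.nii.gz --t1 t1.nii.gz \
    --flair flair.nii.gz --prob GM gm.nii.gz --prob WM wm.nii.gz \
    --prob CSF csf.nii.gz --lesions lesions.nii.gz --output naa_hr.nii.gz
```

Every run writes a JSON manifest (config, input hashes, per-iteration
diagnostics) sufficient to reproduce the output bit for bit.

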