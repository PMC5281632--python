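# Methods

## Model and assumptions

The observation model is `y = H(x)`: the low-resolution metabolite map `y`
is a blurred, block-averaged rendering of an underlying high-resolution map
`x` on a grid with `scale` (default 2) times more voxels per axis. `H` is a
separable sinc-shaped point-spread function — the PSF of phase-encoded MRSI,
whose first zero falls at one nominal (low-resolution) voxel size — followed
by a boxcar average over each `scale`-block. Reconstruction assumes
approximate stationarity: at the target resolution, every local patch has
many similar patches nearby, so a voxel can be estimated as a weighted
average of its search-volume neighbors (non-local means). Anatomy
(T1-weighted, FLAIR, soft GM/WM/CSF memberships) is assumed co-registered;
scanner affines are composed (`MRSI_affine⁻¹ · MRI_affine`) rather than
estimated, which is appropriate for sequential same-scanner acquisitions.

The iteration alternates the non-local reconstruction pass with a mean
correction that adds each block's data residual `y_p − H(x)_p` back to all
voxels of the block. With an identity PSF this projects the iterate exactly
onto the set of maps whose block means equal `y`; with the sinc PSF the
projection is approximate and a small irreducible residual remains.

## Weights

* **MRSI weights** (self-similarity): `w ∝ exp(−‖N̂ᵢ−N̂ⱼ‖²/(2N hᵢ²))` over
  patches of the metabolite map. `hᵢ` is the noise scale estimated from
  pseudo-residuals `εᵢ = √(6/7)(xᵢ − mean of the 6-neighborhood)`; the √(6/7)
  factor makes `E[ε²]` equal the noise variance for white noise (verified on
  unit-variance Gaussian volumes in the tests). `hᵢ²` is the mean of `ε²`
  over the in-bounds search volume of voxel i — under Gaussian weights every
  candidate has non-zero weight, so "the voxels contributing to the
  reconstruction" is the whole (truncated) search cube.
* **MRI weights** (anatomy-guided): the same exponential patch kernel
  evaluated on each anatomical channel, multiplied by the tissue-overlap
  gate `(1/K) Σₖ pᵢₖ pⱼₖ`. Here the noise scale is the **standard deviation
  of the channel's intensities over the patch neighborhood** (`local_patch_sd`)
  — the general definition of `h` for this weight family. A pseudo-residual
  estimate would collapse to the floor on nearly noise-free anatomy and
  degenerate the weights to self-weights; the local patch SD instead adapts
  the tolerance to local tissue contrast (small in flat tissue, large at
  boundaries). With both T1 and FLAIR, patch distances are concatenated:
  `Σ_c S_c/h_{i,c}²` with `N` summed over channels.
* **Blending**: `α = 1` inside lesions (metabolite-driven), `0` elsewhere
  (anatomy-driven); a constant-α policy is available. Voxels with zero
  membership in every tissue class (outside the brain, or lesion voxels when
  the segmenter treats lesions as an outlier class) have no MRI weight mass
  and fall back to the MRSI weights.

## Numerical choices

* Patch cube of size 8 has no center voxel; it spans offsets [−4, +3] per
  axis (the convention of `scipy.ndimage.correlate1d` with even-length
  weights). Boundary patches truncate to in-bounds voxels, and the `N` in
  the exponent is the actual pairwise overlap count.
* Search volume: cube of half-width 5 (11³), configurable.
* Noise floors: `h` is floored at `1e-6 ×` the median absolute image value
  (or 1e-12 for all-zero images); identical patches then still receive equal
  weights instead of dividing by zero.
* Convergence: relative L2 change `‖xᵗ−xᵗ⁻¹‖/‖xᵗ⁻¹‖ ≤ 1e-3` (stabilizer
  1e-12). A per-voxel maximum relative change is unusable on metabolite maps
  because background voxels are near zero and turn the ratio into noise.
  `max_iters` defaults to 10; non-convergence is reported, not raised.
* Mean-correction sign: `x̂ = x + (y_p − H(x))`, the direction that moves
  block means toward the data; with an identity PSF block means match `y`
  to machine precision (tested).
* PSF kernel: sinc sampled at high-resolution offsets, truncated at 2
  low-resolution voxels (two lobes), normalized to unit sum; applied
  separably with reflective boundaries.
* The reconstruction pass is vectorized over search **offsets**: for a fixed
  offset δ the patch distances between all voxels i and candidates i+δ are a
  box-filtered squared-difference image, so a pass costs a few separable
  filters per offset instead of a per-voxel loop. The test suite checks this
  fast path against a literal nested-loop implementation to 1e-8.
* Everything is deterministic: identical inputs give bit-identical outputs;
  the only randomness in the package lives in the phantom generators and is
  seeded.

## Synthetic data

The generators provide desk-scale stand-ins for the two validation
experiments; they are first-class, tested code.

* **Cylinder phantom**: a 180 mm water cylinder with seven 40 mm cylinders
  on a 60 mm ring; acetate 0 (empty), then 6–16 mM in 2 mM steps, so the
  cylinder-5 : cylinder-2 and cylinder-7 : cylinder-3 ratios are exactly 2.
  Modeled on a 5 mm grid (40×40×6 voxels) and acquired at 10 mm; the
  experiment adds noise of σ = 0.5 mM on the high-resolution map (SNR ≈
  12–32 over the cylinders, "moderate noise"). The T1-like volume gives each
  compartment a distinct constant intensity, and the manual cylinder
  segmentation enters the anatomy weights as one-hot memberships.
* **Brain phantom**: nested ellipsoids give a WM core, GM shell and thin CSF
  rim with smoothstep transitions (memberships sum to 1 inside the head);
  default 64³ voxels at 1 mm. NAA is the membership mixture with GM 30,
  WM 25, CSF 0 (a.u.), overridden to 20 inside lesions. Lesions are random
  spheres of radius 2.5–5.5 voxels (5–11 mm diameter, the clinical MS range,
  so lesion cores are resolved on the ×2-coarser grid) seeded in deep WM
  (normalized radius < 0.4), matching the periventricular/deep-WM
  distribution of MS lesions; presets mild/moderate/severe use 3/8/15
  seeds. The segmenter semantics treat lesions as an outlier class: lesion
  voxels carry zero membership in the GM/WM/CSF maps and are covered by the
  binary lesion mask — this is what makes the α = 1 rule necessary there.
  T1-like and FLAIR-like volumes are membership mixtures with
  lesion overrides (T1 mildly hypointense, FLAIR hyperintense) plus 1%
  Gaussian noise of the brightest tissue (σ 1.4 / 1.9 a.u.).
* **Acquisition simulator**: white Gaussian noise (σ = 2 a.u. by default,
  read as a standard deviation) is added to the high-resolution map; each
  decimated axis is low-pass filtered with a 31-tap symmetric equiripple
  (Chebyshev-approximation) FIR whose transition band is centered on the
  target Nyquist frequency — the canonical decimation corner. An odd-length
  symmetric FIR applied centered is exactly zero-phase and preserves
  constants (unit-normalized taps) and plateaus wider than its ±15-voxel
  support; an infinite-impulse-response realization of comparable order was
  rejected because its non-decaying ringing depressed all plateau
  concentrations by several percent, which is neither edge-preserving nor
  consistent with an unbiased acquisition. Decimation samples the filtered
  signal at each block center; for even factors the center falls between
  samples and is linearly interpolated, keeping the low-resolution grid
  exactly nested under the high-resolution one.

**What the phantoms do not emulate**: real cortical folding and tissue
texture, B0/B1 inhomogeneity, spectral fitting errors in the quantified
maps, registration error between MRI and MRSI, and scanner-specific PSFs
beyond the sinc model. Passing tests therefore demonstrate correctness of
the algorithm and its behavior under the stated simulation protocol, not
in-vivo performance.

## Evaluation

* SSIM is computed **once globally** over the brain mask with both stability
  constants zero (valid because metabolite values in brain are bounded away
  from zero); sample statistics use n−1 normalization. It is not the
  windowed SSIM of general image-processing libraries.
* Welch's t (unequal variances, Welch–Satterthwaite df, two-sided) compares
  lesion voxels against "white matter surrounding lesions" (NWM): the lesion
  mask dilated by 2 voxels (26-connectivity), minus the lesions, intersected
  with WM-dominant voxels (p_WM > 0.5). Radius and connectivity are
  parameters; "surrounding" has no canonical definition.
* Cohen's d uses the classical pooled SD with n−1 weighting.
* ROI summaries report median and quartiles with the linear-interpolation
  quantile rule.

## Known limitations

* Convergence of the alternating iteration is linear with an empirical
  contraction factor around 0.75–0.8 per iteration on the brain phantom; the
  default tolerance is reached in 4–5 iterations, but much tighter
  tolerances would need proportionally more iterations.
* With the sinc forward model and the FIR acquisition filter there is
  deliberate model mismatch (as in practice); the post-correction data
  residual is then not exactly monotone across iterations and a small floor
  remains.
* On a clean, compact-support acquisition all methods' surrounding-WM
  medians sit within ≈0.1 a.u. of the data ceiling, so median-based
  rankings between methods in that region are within simulation noise; the
  contrast statistics (effect size, SSIM) are the discriminating metrics on
  this phantom.
* Single-scale only: a large resolution gap (scale > 4) leaves the
  downsampled tissue priors too mixed to guide reconstruction; repeated
  invocation is possible but no multi-scale cascade is built in.
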