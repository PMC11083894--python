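# Methods

## Conventions

Stacks are arrays indexed `(z, y, x)`, 0-based; all physical lengths are in
µm and volumes in µm³. Voxel dimensions always come from configuration,
never from TIFF metadata: acquisition geometry is part of the experimental
record, and a silent metadata mismatch is a classic source of anisotropy
bugs (if embedded metadata conflicts, the configured value wins with a
logged warning). The reference geometries are 0.103 × 0.103 × 0.15 µm
(63× oil, spinning-disk) and 0.325 × 0.325 × 0.35 µm (20× air, whole-cell
quantification); stacks are assumed 16-bit, the native depth of the sCMOS
cameras involved.

## Segmentation model

A mitochondrial "object" is a maximal 26-connected set of foreground
voxels after thresholding — one fused network region is one object, however
large. 26-connectivity is the default because tubules routinely traverse
voxels diagonally; 6-connectivity fragments them.

The mask is built from a filtered copy of the stack, in this order:

1. **3D median filter**, box neighborhood of radius 1 voxel per axis
   (configurable), reflecting at edges. Removes impulse noise; also erodes
   structures near the voxel scale (see *Limitations*).
2. **White top-hat**: the input minus its grayscale opening by an
   ellipsoidal element of physical radius 1.0 µm by default, voxelized per
   axis so the element is spherical in µm on anisotropic grids. This
   removes the diffuse dye background (the dominant artifact of JC-1 and
   CMXRos staining) while passing structures thinner than the element.
   The element must be chosen larger than the thickest genuine structure:
   an object wider than the element survives the opening and is *subtracted
   from itself*, leaving a hollow shell that then splits or vanishes at
   threshold. The default suits tubules up to ~1 µm diameter; analyses of
   thicker content should raise `tophat_radius_um`.
3. **Constant threshold**, boundary-inclusive (≥). The value is a required
   config parameter shared across all stacks of an experiment so volumes
   stay comparable; `suggest_threshold` offers mean + k·SD (k = 3) of a
   user-designated background region as a starting point, but nothing is
   chosen silently. Inclusivity makes the degenerate limits clean
   (threshold 0 → all-true; above max → all-false).
4. **Labeling** with deterministic label order (raster order of each
   component's first voxel), so reruns are byte-identical.

Per-object intensity (the ΔΨm proxy) is measured on the *input* stack, not
the filtered one: the filters exist to shape the mask, and letting them
touch the intensity readout would distort the membrane-potential signal.
Volumes are exact voxel counts times the voxel volume. Size classes:
< 2 µm³ (fragmented), 2–10 µm³ inclusive on both ends (medium), > 10 µm³
(network).

No watershed splitting is attempted: touching mitochondria genuinely are
one connected object under this definition, at the cost of overestimating
object size when resolution merges close neighbors.

## Per-cell morphometry

The whole-cell (Calcein) channel is thresholded with its own constant and
hole-filled (6-connected background regions not reaching the array border
become foreground), since vacuoles belong to cell volume. The nucleus
(Hoechst) channel is thresholded and intersected with the cell mask before
subtraction, so cytoplasm = cell − nucleus can never go negative even with
noisy masks. Multi-nucleated cells pool all nuclear voxels. A cell whose
nucleus mask equals its cell mask has zero cytoplasm; the
%-volume-per-cytoplasm field is then reported as undefined rather than
dividing by zero. Group summaries use the sample SD (n − 1); a single-cell
group reports SD 0 with an explicit `sd_defined = False` flag. Total
intensity columns are flagged session-bound: dye loading varies between
staining sessions, so intensity is only comparable within one session.

## Photostability model

Ten consecutive z-stacks of one field give, per ROI (3–5 rectangles of
100–150 µm²), the mean intensity over the maximum intensity projection,
normalized to that ROI's first acquisition. Time is rescaled to [0, 1]
across the series, so a slope is the relative change over the whole series
— the only scale on which slopes of magnitude 0.1–0.3 are physically
consistent with signals that remain positive.

The trend model is a Gaussian regression with structure in both moments,
μ(t) = α + βt (or constant α) and log σ(t) = γ + δt (or constant γ), fitted
by maximizing the likelihood numerically (Nelder–Mead from α, β at their
OLS values, γ at the log residual SD, δ = 0; tolerance 1e−8 on −logL).
"Non-linear" here refers to the joint ML estimation of location and
dispersion, not to a curvilinear mean. Model selection minimizes
−logL + k, the minus log-likelihood penalized by the parameter count — an
AIC variant on the natural-log scale; ties go to fewer parameters. For the
linear-location/constant-dispersion model the ML slope equals the OLS
slope, which the tests use as an independent closed-form check (the R
machinery this mirrors is not exercised here).

Two numerical choices matter:

* **The reference acquisition is excluded from the likelihood.** Relative
  intensity at t = 0 is identically 1 — it is the normalizer — so it
  carries no information, and for any time-varying dispersion model those
  exact points drive σ(0) → 0 and the likelihood to +∞. Fitting on
  acquisitions 2..n removes the degeneracy without touching the estimand.
* **σ(t) is floored at 1e−9** inside the objective, so noiseless data
  (residual SD → 0) return their exact slope with a finite objective and a
  `degenerate` flag instead of a diverging optimizer.

Self-normalization has a statistical side effect worth knowing: noise in
the first acquisition becomes a shared multiplicative error for the whole
ROI trajectory. That inflates residual variance without adding slope
variance, which makes the penalized criterion *more* conservative about
declaring a trend — under no planted trend, the constant-location model is
selected in ~93% of replicates at the study's noise level, comfortably
above the 90% working criterion.

Between-ROI spread is summarized by `fold_variation`, the max/min of
relative intensities across ROIs at a given acquisition (the quantity
behind "1.5–2-fold variation between cells").

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, not
optics: tubules are fixed-step (0.2 µm) random walks with a curvature
bound, painted as spheres of the tubule radius along the centerline and
voxelized on the anisotropic grid; a `fraction_globular` of objects are
compact spheres 1–1.5× the tubule radius (fragmented mitochondria are
small, and the cap keeps them inside the top-hat element). Placement
rejects positions outside the cytoplasm and, when a minimum separation is
set, walks snake around previously placed objects (the margin includes
0.35 µm for stamp quantization, so planted voxels never leak outside the
voxelized cell). Object intensities are drawn Normal(`potential_mean`,
`potential_sd`) — the ΔΨm proxy — clipped below at 5% of the mean.
Rendering adds a uniform diffuse background, blurs with an isotropic-in-µm
Gaussian PSF (σ 0.15 µm default), then applies Poisson noise on a
photon-scaled copy plus Gaussian read noise, in that physical order, and
quantizes to 16-bit. Planted objects that touch are merged in the ground
truth by 26-connected labeling of the union mask, mirroring the object
definition.

Presets (test scale: 32×128×128 at 20× geometry, ~0.5 s per cell, against
the instrument's native 70-slice stacks):

* **default / mesoangioblast-like**: 30 objects (population preset draws
  round(Normal(30, 12))), tubule radius 0.5 µm, lengths 2–10 µm,
  separation 1.2 µm — wide enough that blur halos of bright neighbors do
  not bridge at the working threshold, so object *counts* are exactly
  recoverable.
* **myotube-like**: 48×192×192 field, round(Normal(167, 71)) objects,
  radius 0.55 µm, lengths 6–25 µm, no separation constraint — dense
  networks touch and merge, as in real myotubes. Lengths are sized so the
  planted total mitochondrial volume is ~12× the mesoangioblast preset's,
  the fold observed upon myogenic differentiation.
* **recovery preset**: 15 straight-ish tubules of radius 0.7 µm (~2 voxels),
  lengths 5–10 µm, ≥ 2 µm apart, per-object intensity CV 3%, SNR ≈ 17.
  These are the conditions under which per-object *volumes* are
  recoverable to ±15% (measured spread ≈ ±10% around truth at threshold
  80); see *Limitations* for why thinner or dimmer objects cannot meet
  that bound.

At full Table-scale morphology (30 objects filling ~17% of a
mesoangioblast's cytoplasm without touching) non-overlapping random
placement is geometrically infeasible at the test field size, so the
presets scale object volumes down while preserving the object-count
distributions and the 12× between-group volume fold — the quantities the
validation asserts.

Series mode re-renders the same field per acquisition with the clean image
(objects *and* background — everything is dye) multiplied by
1 + `decay_slope`·tᵢ, fresh noise each time, optionally a smooth
multiplicative gain field per acquisition, and, with `morphology_change`,
half of the tubules ≥ 7 µm replaced from the sixth acquisition by three
spheres of a third their volume spaced at 10/50/90% of the former
centerline (total volume preserved; shorter tubules are left intact because
their fragments would re-merge under the PSF). The lightweight
`simulate_intensity_series` generates ROI trajectories directly —
baseline·(1 + (β + b_r)t + ε), b_r a per-ROI slope effect, ε per-observation
noise — for Monte-Carlo studies where rendering stacks would be waste; a
static per-ROI gain is deliberately not simulated because self-normalization
cancels it exactly.

All randomness flows from a single seed (populations spawn per-cell
sub-seeds), so every output is bit-reproducible.

## What passing tests do and do not show

The simulations validate the pipeline's bookkeeping (conservation,
determinism, geometry handling), its statistical machinery (slope recovery
to ±0.02 at the study's noise level, model-selection behavior), and its
segmentation under conditions where the truth is unambiguous. They do not
validate performance on real microscopy: no optical PSF model
(Gibson–Lanni), no pinhole cross-talk, no depth-dependent background, no
cell movement between acquisitions, no deconvolution artifacts (the
pipeline accepts pre-deconvolved or raw stacks identically and treats
deconvolution as an external pre-step), and no JC-1 aggregate/monomer
spectral chemistry.

## Limitations

* **Per-object volume accuracy is resolution-bound.** With a constant
  threshold, the recovered boundary of an object scales with its
  brightness; combined with median erosion and partial-volume effects,
  objects thinner than ~2 voxels in any axis or with per-object intensity
  more than ~10% from the group mean acquire volume biases beyond ±15%.
  Counts remain exact well past the point where volumes degrade. This is a
  property of constant-threshold segmentation generally, not of this
  implementation.
* **Merged neighbors.** Objects closer than the blur scale merge; their
  combined size is overestimated. The tool accepts this (an "object" is a
  connected region) rather than guessing a split.
* **Intensities are session-bound** and never normalized across staining
  sessions; the reports only flag, not correct, this.
* **The top-hat element is a tuning choice**: structures wider than it are
  destroyed, not preserved (see above).
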