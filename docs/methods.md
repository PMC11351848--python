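# Methods

`coroseg` extracts coronary arteries from contrast-enhanced cardiac CT
(CTA) volumes with a cascade of two 2D segmentation networks wrapped in
classical vessel-image processing. This note documents the model and the
numerical choices; the README shows how to run it.

## Pipeline overview

1. **Isotropic resampling.** The volume is resampled to 1 mm isotropic
   voxels (linear interpolation; nearest-neighbour for masks). All later
   scale parameters are therefore interchangeable between voxels and mm.
2. **Coherence-enhancing diffusion (CED).** Structure-tensor-guided
   anisotropic diffusion denoises the volume while preserving tubular
   structures (below).
3. **Min–max normalization** to [0, 1] over the volume. A constant volume
   is rejected as an upstream failure rather than silently zeroed.
4. **Heart segmentation (stage 1).** A ResDense U-Net segments the heart
   on whole axial slices; the largest 3D connected component is kept (one
   heart) and its bounding box, padded by an 8-voxel margin, defines the
   region of interest (ROI). The margin keeps the epicardial surface —
   where the coronaries run — inside the box.
5. **Vesselness fusion.** 3D multiscale Frangi vesselness is computed on
   the ROI and added to the intensity image (clipped to [0, 1]). Weight 0
   reproduces the intensity-only ablation bit-for-bit.
6. **Coronary segmentation (stage 2).** A second ResDense U-Net segments
   the coronaries on centre-cropped/zero-padded ROI slices; predictions
   are thresholded at 0.5 (strict) and re-embedded into the original grid.
7. **Evaluation.** Dice, Jaccard, precision and recall from voxel-level
   confusion counts, computed per 3D case and averaged unweighted across
   cases. Two empty masks score 1.0 with a flag, so per-case averages stay
   defined.

## Coherence-enhancing diffusion

At each voxel the structure tensor J_ρ = G_ρ ∗ (∇u_σ ∇u_σᵀ) is formed with
gradient (noise) scale σ = 0.5 mm and integration scale ρ = 2 mm. With its
eigenvalues ordered µ1 ≥ µ2 ≥ µ3, the eigenvector V3 of the smallest
eigenvalue is the direction of least intensity variation — along a tube's
axis. The diffusion tensor keeps diffusivity 1 along V3; the two cross
directions get a diffusivity that drops to a floor (0.01) where the ratio
µ2/µ3 flags a tube-like neighbourhood (large for lines, ≈1 for blobs,
plates and flat regions) and relaxes toward 1 elsewhere so homogeneous
tissue is still denoised isotropically. The switch is
exp(−g / (µ2/µ3 − 1)²) with gain g = 1e-3.

Numerics: explicit divergence-form steps with time step 0.15 (stability
bound 1/6 for the 3D explicit scheme, enforced at construction), fluxes
averaged onto cell faces before differencing — so total intensity
telescopes and the volume mean is conserved to rounding — and zero-flux
boundaries. Because the mixed-derivative terms of an anisotropic explicit
scheme do not guarantee a discrete max principle, each step clips the
field to the running intensity range; diffusion cannot create new extrema
in the continuum, so the clip only removes numerical overshoot. Five
iterations by default. A constant volume is an exact fixed point.

## Multiscale Frangi vesselness

With Hessian eigenvalues ordered |λ1| ≤ |λ2| ≤ |λ3|, the discriminant

    v(σ) = (1 − exp(−Ra²/2α²)) · exp(−Rb²/2β²) · (1 − exp(−S²/2c²)),
    Ra = |λ2|/|λ3|,  Rb = |λ1|/√|λ2 λ3|,  S = ‖H‖_F,

is evaluated per voxel and scale, with v = 0 where λ2 ≥ 0 or λ3 ≥ 0
(bright-vessel rule; a conjunctive variant, the plain product |λ2 λ3| in
Rb's denominator, and the background variant 1 − exp(−S²/c) are
selectable flags — the squared default is the dimensionally consistent
form: with c set from the Hessian-norm maximum it saturates for the
strongest structures regardless of the image's absolute gray scale,
whereas the un-squared variant's value depends on the magnitude of S).
α = β = 0.5. The multiscale output is the per-voxel maximum over
σ ∈ {2, …, 8} voxels, covering the radius range of coronary lumens on a
1 mm grid.

* **Scale normalization.** Second derivatives are multiplied by σ²
  (γ = 2), the condition for responses to be comparable across scales so
  that the argmax tracks the vessel radius. On ideal cylinders of radius
  2/3/5 voxels the selected scale lies within one voxel of the radius.
* **The c rule.** c is recomputed per scale as half the maximal Hessian
  Frobenius norm of that scale's field; computing it per scale keeps the
  background term consistent as σ² rescales the Hessian. A fixed c is
  available. Fields whose maximal norm is below 1e-10 are treated as
  structureless (guards constant volumes against rounding residue).
* **Derivative kernels.** Sampled Gaussian derivative kernels are
  moment-corrected after truncation (support 6σ): the smoother sums to 1,
  the first derivative responds to x with exactly 1, the second
  derivative has zero DC gain and responds to x² with exactly 2. Without
  the correction a constant image produces a spurious second derivative
  and polynomial responses are biased by a few percent.
* **Analytic limits** (α = β = 0.5, S² ≫ c): an ideal bright tube
  (0, −L, −L) scores 1 − e⁻² ≈ 0.8647; an ideal blob (−L, −L, −L) scores
  (1 − e⁻²)·e⁻² ≈ 0.1170. Both are exercised by the tests and the
  acceptance script.

## Network

A U-Net with five hierarchy levels by default (configurable; the
desk-scale experiments use three). Each level block stacks two
conv(3×3)–ReLU–BN units — that operation order is the default, with the
conventional conv–BN–ReLU selectable — and the block's skip form is
configurable: plain, residual (additive identity shortcut; 1×1 projection
when widths differ), dense (input concatenated onto the output), or
**resdense**: two residual sub-blocks linked by a dense concatenation of
the block input with the second sub-block's output. In the encoder every
block doubles the feature depth (base width 16 after the first block),
2×2 max pooling halves resolution between levels, the decoder mirrors
with parameter-free 2× nearest-neighbour upsampling plus concatenation of
the matching encoder features, and a 1×1 convolution + sigmoid emits
per-pixel probabilities. Input spatial size must be divisible by
2^(levels−1).

The layers are implemented directly in NumPy (channels-last im2col
convolutions, batch normalization with running statistics, hand-written
backward passes) so training and inference run anywhere NumPy does. The
sigmoid head clamps outputs to [1e-7, 1−1e-7]: float32 saturates beyond
|logit| ≈ 17, which would break the probability contract and the loss's
epsilon convention.

## Training

* **Patches.** One patch per axial slice of the (vesselness-enhanced)
  ROI, centre-cropped/zero-padded to 256×256 (64×64 at desk scale), each
  standardized to zero mean / unit variance. Slices whose mask patch is
  empty are excluded from training; at inference every slice is
  processed.
* **Loss.** L = BCE + (1 − softDice) with unit weights summed (not
  averaged) — the convention is pinned by a closed form: prediction ≡ 0.5
  against a half-ones target gives ln 2 + 0.5 ≈ 1.1931. Probabilities are
  clipped at ε = 1e-7, which is also the soft-Dice denominator epsilon.
* **Schedule.** Adam from 1e-4; validation Dice is monitored with an
  improvement threshold of 1e-4 over the best so far; the learning rate
  halves after 3 consecutive non-improving epochs (the LR counter then
  resets), training stops after 5; batch 16; at most 500 epochs; global
  gradient-norm clipping at 1.0 (post-clip norms are recorded). The
  weights of the best-validation epoch are restored at the end.
* **Split.** 80/20 train/validation **by case**; no case contributes
  patches to both sides.
* **Head initialization.** The output bias starts at the logit of the
  training foreground rate. With very sparse targets (coronaries occupy
  ~1–3% of ROI pixels) a zero bias wastes the first epochs unlearning an
  implicit 50% foreground assumption.
* **Epoch multiplier.** On very small synthetic corpora an "epoch" may
  iterate the reshuffled patch set k times, so optimizer steps per epoch
  are comparable to a full-size corpus while every per-step condition
  (lr, batch, clipping) is unchanged. The default study corpus is large
  enough that it uses k = 1.

## Synthetic phantoms

Phantoms emulate the structure the cascade targets: a bright ellipsoidal
heart (intensity 0.5) containing brighter tubular trees (peak 0.78, radii
2–4 voxels) against dark background (0.05), plus Gaussian noise (sd
0.08), with exact paired masks for both stages. Default study geometry is
64³ at unit spacing. Two properties of real coronary CTA drive the
default rendering:

* **Base-to-apex trees.** Real coronary trees course from the heart base
  toward the apex, so nearly every axial slice of a heart ROI contains
  vessel cross-sections — which matters for a slice-wise model trained
  with the empty-patch exclusion rule (a model that never sees negative
  slices hallucinates on them). The generated tree has a long main trunk
  spanning ~80% of the heart's z-extent, a shorter secondary trunk, and
  lateral branches.
* **Radial profile.** The default renders tubes at full contrast out to
  the lumen boundary (`vessel_profile="flat"`), which keeps the truth
  masks unambiguous. A Gaussian radial profile (`"gaussian"`, sigma =
  r/2, peak on the centerline) is available to emulate the
  partial-volume fading of thin vessels in CT; it makes the boundary
  voxels genuinely ambiguous and lowers the ceiling of any
  intensity-driven model.

Tubes are straight segments joined at nodes (no curvature model); truth
masks are exact distance-to-centerline voxelizations, so mask volumes
converge to the analytic cylinder/sphere/slab volumes as radii grow.

What the phantoms do **not** model: CT physics beyond the radial profile
(beam hardening, streak artifacts), anatomical neighbours of the heart
(lungs, sternum, descending aorta — the stage-1 task is much easier here
than on real CTA), curved and tapering vessels, pathology (stenoses,
calcifications). Passing the desk-scale study shows the pipeline's
machinery is sound and that vesselness fusion helps under controlled
conditions; it does not certify clinical performance.

## Desk-scale study

`coroseg.experiments.run_phantom_study` trains the full cascade on CPU:
10 phantom cases (8 train / 2 held out), a 3-level base-8 network, 64×64
patches, heart model ≤ 8 epochs, coronary models ≤ 20 epochs with epoch
multiplier 2. The study evaluates held-out cases through the *real*
cascade (predicted heart → ROI → coronary model) and reports heart Dice,
coronary Dice with vesselness fusion, and coronary Dice for the
intensity-only ablation trained identically. These sizes were chosen so
the whole study runs in minutes on a single core while both stages reach
their quality plateaus.

One result deserves an honest caveat. On the default phantoms the
intensity-only ablation slightly *outscores* the vesselness-fused model.
The mechanism is visible in the fused inputs: phantom vessels are
rendered at full contrast, so `clip(vol + v, 0, 1)` saturates the lumens
at 1.0 and erases the boundary gradient the plain model exploits.
Shape-based enhancement earns its keep on faint, thin vessels in
cluttered anatomy — partial-volume-dimmed distal branches — which is
exactly what the simple phantom does not emulate (and, with the
`"gaussian"` profile, what no intensity cue can fully recover either).
The study therefore validates the machinery of the fusion path — its
bit-exact weight-0 ablation, its end-to-end trainability, its
segmentation quality — but not a fusion *benefit*, and reports the
signed Dice difference rather than asserting an ordering.

## Known limitations

* The NumPy backend is single-threaded and desk-scale; production-scale
  256×256 training is out of its scope.
* CED parameters (iterations, scales, gain) are heuristics exposed in the
  configuration; they were not tuned against clinical data.
* The ROI is a bounding box; a masked (background-zeroed) ROI variant is
  a flag away but untested against real data.
* Orientation matrices are carried opaquely; volumes are assumed to be
  axially sliceable along array axis 0.
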