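# Methods

## Problem and approach

Pixel-accurate annotation of infected lung regions (ground-glass opacity and
consolidation) in chest CT is the main cost in training segmentation
networks for pneumonia quantification.  `atstseg` implements a
semi-supervised dual-branch training scheme that supplements a small
expert-annotated set with pseudo-labels obtained for free from the CT scale
itself: inside the lung, voxels with Hounsfield-unit values in
`[-750, 50]` HU are marked as lesion (`generate_pseudolabel`).  This band is
the union of the ground-glass opacity interval `[-750, -300]` and the
consolidation interval `[-300, 50]`; the package assigns the shared boundary
value -300 HU to consolidation so the two subtypes partition the band.  The
pseudo-labels are noisy by construction — vessels, airway walls and other
healthy dense tissue fall in the same attenuation range — and no
morphological cleanup is applied: coping with that noise is precisely what
the training method is for.

Two structurally identical U-Nets are trained jointly:

* the **clean branch** (parameters θ) minimises
  `L_clean = L_mseg + λ·L_pseg-clean`, where `L_mseg` is the segmentation
  loss on expert-labelled slices and `L_pseg-clean` the same loss of the
  clean branch's predictions on pseudo-labelled slices against the HU
  pseudo-label;
* the **noisy branch** (parameters θ′) minimises
  `L_noisy = λ·L_pseg-noisy` against a per-image target chosen by the
  switching rule below, and additionally tracks the clean branch through an
  exponential moving average
  `θ′_t = ε·θ′_{t-1} + (1-ε)·θ_t` with the adaptive coefficient
  `ε(i) = 1 - 0.2·exp(-8 i / iters)` (0.8 at the start of training, rising
  towards 1).

The segmentation loss throughout is `L_seg = 0.5·(L_dice + L_BCE)` with a
Dice smoothing constant of 1 on the summed formulation.

### Target switching

Each pseudo-labelled image in a batch is scored with

    S_lovasz = LEV(GT_pseudo, P_clean) / exp(div(GT_pseudo, P_noisy))

where `LEV` is the Lovász extension of the Jaccard loss evaluated at the
clean branch's per-pixel error vector (sorted-error accumulation against the
discrete Jaccard gradient; equal to `1 − IoU` on binary inputs), and `div`
is the mean symmetrized Bernoulli Kullback–Leibler divergence between the
pseudo-label (lifted to a probability map clamped to `[1e-6, 1-1e-6]`) and
the noisy branch's prediction (Jensen–Shannon available via
`divergence="js"`).  The per-batch mean score enters a sliding window
(default length 100); once the window has filled, the threshold τ is the
h-th percentile of the window (default h = 50, linear interpolation).  An
image with `S_lovasz − τ ≥ 0` (ties switch) has its weak-branch target
replaced by the clean branch's prediction binarised at 0.5; otherwise — and
always during the warm-up before the window fills — the HU pseudo-label is
kept.  Decisions are taken per image against the shared τ; the score is
computed on the forward pass preceding the gradient step, and τ is updated
before the decisions of the same iteration.

### Two readings of the clean branch's pseudo-stream target

`clean_pseudo_target` selects what `L_pseg-clean` supervises against:

* `"hu"` (default): the HU pseudo-label itself — the literal reading of the
  objectives.  Information then flows only from the clean branch to the
  noisy branch (gradient on `L_pseg-clean`, EMA blending, switched
  targets); nothing couples the noisy branch back, and inference uses the
  clean branch alone.  Under this reading, toggling the target switching
  changes the noisy branch but leaves the clean branch's trajectory — and
  therefore test performance — bit-for-bit unchanged under a fixed seed
  (the two dual-branch benchmark arms double as a determinism check).
* `"noisy"`: the noisy branch's *soft* prediction — the mean-teacher
  consistency reading, under which the pseudo-stream loss is still
  `0.5·(L_dice + L_BCE)` but its target is the temporal-ensemble twin.
  This closes the loop (switching then reaches the inference branch);
  soft rather than binarised targets are essential, because sharpened
  self-targets make the all-background prediction a self-consistent
  collapse point.  An additional mean-squared consistency term is also
  available (`consistency_weight`, default 0).

On the phantom benchmark both readings let the pseudo-labelled stream help
the clean branch; `"hu"` helps more and is the default.

## Parameters that matter

| parameter | default (desk) | published profile | meaning |
|---|---|---|---|
| `side` | 64 | 256 | slice edge length after resampling (px) |
| `base_width`, `depth` | 8, 3 | 16, 4 | U-Net first-level channels / pooling levels |
| `iters` | 400 | 40 000 | SGD iterations |
| `batch_labeled`+`batch_pseudo` | 4+4 | 64+64 | batch composition |
| `lr`, decay | 0.05, ×0.1 | 0.01, ×0.01 | initial learning rate and total exponential decay |
| `momentum` | 0.9 | 0.9 | SGD momentum |
| `lambda_max`, `ramp_fraction` | 1.0, 0.1 | same | pseudo-loss weight, sigmoid ramp length |
| `window_len`, `h_percentile` | 100, 50 | same | score window and τ percentile |
| `ema_amplitude`, `ema_rate` | 0.2, 8 | same | constants of the adaptive ε schedule |
| `dice_smooth` | 1.0 | same | Dice smoothing constant |
| `norm` | `"group"` | same | backbone normalisation (`"none"` for plain conv-ReLU) |
| `clean_pseudo_target` | `"hu"` | same | pseudo-stream target for the clean branch (see above) |

The desk profile exists so the full method runs end-to-end in seconds to
minutes on one CPU; the published profile keeps the method's stated constants.  At 400
iterations a 100× learning-rate decay (the published-profile choice) leaves the
last quarter of training with a negligible step size, so the desk profile
decays by 10× instead and starts at 0.05 — chosen once while designing the
desk-scale benchmark, before any acceptance measurement, and applied
identically to every training arm.

Augmentation follows the published recipe: random crop (scale 0.8–1.0,
resized back bilinearly, nearest-neighbour for masks) and left–right flips
with probability 0.5.

## Preprocessing and I/O

Volumes are read from NIfTI or DICOM series (rescale slope/intercept
applied; slices sorted by `ImagePositionPatient`).  HU values are clipped to
`[-1200, 600]` and mapped affinely to `[0, 255]` (`hu_clip_normalize`), then
slices are resampled to `side × side` and scaled to `[0, 1]`.  Masks are
written as unsigned 8-bit NIfTI with the reference volume's geometry;
continuous images are resampled bilinearly and masks nearest-neighbour so
they stay binary.  Physical volumes use the voxel volume (product of the
header spacing, mm³); the infection ratio is lesion volume over lung volume.

The lung mask can be supplied externally.  The built-in fallback
(`simple_lung_mask`) thresholds air below -320 HU, removes components
touching the in-plane border (exterior air; the z faces are exempt because
lungs continue past the scan range), keeps components above 0.5 % of the
volume, and applies per-slice closing and hole filling (dense lesions would
otherwise leave holes).  It is a morphological stand-in adequate for
phantoms and roughly lesioned lungs, not a learned lung segmenter.

## Evaluation

`dsc` is `2|A∩B|/(|A|+|B|)` in percent; both masks empty returns 100 by
convention, exactly one empty returns 0.  Hausdorff distances are computed
on foreground voxel coordinates in pixel units via the exact Euclidean
distance transform; `hd95` pools the two directed point-to-set distance
lists before taking the 95th percentile with linear interpolation
(`pooled=False` gives the max-of-per-direction variant).  Empty inputs to
`hd95` return the volume diagonal as a flagged worst case.

## The synthetic phantoms

`generate_phantom` builds thin 3D volumes (default 64×64×8 voxels at
1×1×5 mm): an elliptic soft-tissue body (40 ± 15 HU) in exterior air
(-1000 HU) containing two ellipsoidal lungs (-850 ± 40 HU); body size, the
radii, position and mean attenuation of each lung all jitter between cases
(so a small labelled subset does not exhaust the anatomy distribution —
otherwise unlabelled cases would carry no information and the
semi-supervised premise would not be emulated); lesion blobs
strictly inside the lungs whose voxels draw from Normal(-550, 80) truncated
to [-750, -301] (GGO) or Normal(-150, 60) truncated to [-300, 50]
(consolidation), mixed per voxel with probability `ggo_fraction`; vessel-like
distractor tubes with consolidation-range HU inside healthy lung; and
additive Gaussian acquisition noise (σ = 10 HU).  Default lesion radii of
5–12 px give per-slice foreground fractions around 4–8 %, typical of the
moderately-to-severely infected lungs the method targets and large enough
that a small network can learn them within the desk-scale budget.

The distractors reproduce the acknowledged failure mode of HU thresholding —
healthy dense tissue inside the lesion attenuation window — so phantom
pseudo-labels have a strictly positive false-positive fraction, while
aerated parenchyma stays below the band (its HU distribution concentrates
below -750 + 3σ_noise).

What the phantoms do *not* emulate: reconstruction physics, partial-volume
and motion artefacts, pleural effusions, anatomical lobe structure, and the
intensity inhomogeneity of real scanners.  Passing the benchmark therefore
demonstrates that the training mechanics behave as designed under the
intended noise structure, not clinical-grade accuracy.

## Desk-scale benchmark

The ablation benchmark trains three arms — single-branch U-Net on labelled
data only; dual-branch with adaptive EMA; dual-branch with adaptive EMA plus
target switching — on 20 labelled + 40 HU-pseudo-labelled phantom cases
(64×64 slices, 400 iterations, batches 4+4) across 5 seeds and evaluates
DSC per held-out case (each phantom scored over its whole slice stack, the
way volumetric benchmarks report) on 10 test cases per seed.  Per-case
scoring matters: a mean over individual slices lets a single false-positive
pixel on an empty-truth slice drop that slice from 100 to 0, which turns
benign pseudo-label noise into a large artificial penalty.  The expected
direction is U-Net ≤ adaptive-EMA ≤ +ATST as a median tendency, with the
switching arm's `switch_fraction` log rising from exactly 0 (warm-up) to a
positive late fraction.

## Numerical choices and implementation notes

* The backbone is a NumPy U-Net with explicit backpropagation (NHWC
  float32; convolutions as nine shifted contiguous BLAS products on the
  padded array).  Group normalisation (4 channels per group) sits between
  every convolution and its ReLU: without it, small-batch desk-scale
  training collapses to empty predictions on a fraction of seeds, and the
  seed-to-seed variance swamps the method comparisons.  GN has no running
  statistics, so the EMA blends trainable parameters only.  The
  convolution and normalisation forward/backward are verified against an
  einsum oracle and finite differences, and the full network against
  central differences at a kink-free operating point (`norm="none"`).
* Loss gradients are taken in logit space: the cross-entropy term
  contributes `(p − g)/npix` directly, so saturated pixels keep a restoring
  gradient (chaining a clamped probability gradient through the sigmoid
  stalls at `p ≈ 0`).  Logits are clipped to ±60 before the sigmoid purely
  to avoid `exp` overflow.
* Probabilities are clamped to `[1e-6, 1-1e-6]` inside logarithms; the
  Lovász sort is stable, so ties break by pixel order deterministically.
* All randomness flows from one root seed through `numpy.random.SeedSequence`
  spawns (initialisation, labelled sampling, pseudo sampling, two
  augmentation streams), which makes runs bit-for-bit reproducible and lets
  the λ = 0 / EMA-off configuration reduce *exactly* to a single-branch
  supervised loop.
* An all-background ground truth makes the Jaccard set function degenerate;
  `lovasz_extension_value` then returns the mean error.  Both-empty masks
  give DSC 100; empty masks give `hd95` the volume diagonal.
* The EMA update transfers clean weights into the noisy branch (θ′ from θ),
  following the coupling's variable definitions — the reverse of classic
  mean-teacher naming.  It is applied once per iteration after the gradient
  steps; optimizer state is not blended.

## Known limitations

* No batch/group normalisation in the backbone; at full scale this may
  slow convergence relative to modern U-Net variants.
* 2D slice-wise training only; no 3D context.
* The morphological lung mask fails on pleural effusion and consolidations
  touching the chest wall; supply an external mask in such cases.
* Whether a higher Lovász score truly means "prediction better than the HU
  label" is an assumption of the switching rule; the comparison is isolated
  in `select_target` and the score in `s_lovasz`, so the convention can be
  changed in one place.
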