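# Methods

This note documents the model, the numerical choices and the synthetic data
underlying `liunet`, and states what the tests do and do not demonstrate.

## Network

The segmenter is a fully convolutional encoder–decoder of depth 5 operating
on channels-last tensors `(D, H, W, 4)` with the fixed modality order
(t1, t1ce, t2, flair). Each level applies one Inception-style block: three
parallel towers — a 1³ convolution, a 1³ reduction followed by a 3³
convolution, and a 1³ reduction followed by a 5³ convolution — concatenated
along channels. Every convolution is bias-free and followed by batch
normalization (ε = 10⁻⁵, momentum 0.1) and ReLU. Encoder levels are
separated by 2×2×2 max-pooling (four pools, so input dims must be divisible
by 16); the decoder mirrors the encoder with ×2 upsampling, channel
concatenation with the matching skip, and another Inception block. The head
is a 1³ convolution (with bias) to 4 classes plus per-voxel softmax.

**Width schedule.** The reference architecture publishes its depth, kernel
mix and parameter total but not per-level tower widths. The default schedule
here is block output widths (32, 64, 128, 256, 320) across encoder levels,
split (¼, ½, ¼) among the (1³, 3³, 5³) towers, with both bottleneck
reductions at ¼ of the block width; the decoder mirrors levels 4→1. This
lands at 3,447,332 parameters — in the low-millions regime the design aims
for, and ~5.5× below a conventional 3D U-Net's ≈19 M. All widths are
configurable (`ArchitectureConfig.from_widths`).

**Upsampling.** Default is nearest-neighbor ×2 followed by a 1³
channel-adjust convolution (+BN+ReLU). A `transposed` mode implements the
algebraic equivalent of a kernel-2 stride-2 transposed convolution as a 1³
convolution to 8× channels followed by a pixel-shuffle rearrangement.

**FLOPs.** `estimate_flops` counts convolution multiply-accumulates ×2 at a
stated input shape and ignores BN/activation/pooling. FLOP conventions vary
between frameworks by small integer factors, so the figure (211.6 G at 128³
for the default net) is a scale indicator, not an exact claim, and no test
asserts it tightly.

## Numerical engine

No GPU framework is a dependency; `liunet.nn` implements the needed layers
in NumPy (float32 parameters) with analytic backward passes. Convolutions
lower to a single BLAS matmul via im2col; max-pool ties route the gradient
to one winner so gradient mass is conserved on flat regions; batch
normalization uses batch statistics in training mode and running averages at
inference. Adam follows the standard bias-corrected update. Correctness is
established in the test suite by central finite differences on every layer
and end-to-end through a depth-2 network (float64 mode for clean difference
quotients), and by an analytic layer-walk parameter-count oracle evaluated
on randomized configurations. CPU runs are deterministic for fixed seeds;
all randomness (weight init, data order, phantom geometry) flows from
explicit `numpy` generators.

## Objectives

- **Soft Dice**: squared-denominator form
  `(2Σpg + ε)/(Σp² + Σg² + ε)` with ε = 10⁻⁶, computed per class over all
  voxels in the batch and averaged over the three foreground classes;
  background is excluded by default because it dominates voxel counts
  (configurable). The loss is `1 − Dice`.
- **Focal**: `−α_t (1−p_t)^γ ln p_t` averaged over voxels, natural log,
  `p_t` clipped at 10⁻⁷ (gradient zeroed where clipping is active).
  Defaults α = 0.25, γ = 2.0; a per-class α_t vector is supported, as is the
  binary two-term expansion. At γ = 0, α = 1 the loss reduces exactly to
  cross-entropy, which the tests use as an oracle.
- **Combined**: `λ₁·focal + λ₂·dice`, defaults λ₁ = λ₂ = 1 (no reference
  values are published for the λs).

Two normalization modes exist because the source material is ambiguous
between min–max scaling and z-scoring: the pipeline default is min–max
`(X−X_min)/(X_max−X_min)` per modality per subject (the only closed form
printed), with `zscore` (population sd) selectable in the config. Constant
volumes normalize to zeros with a warning. The pipeline order is fixed as
resize → normalize so the output range survives interpolation overshoot;
intensities resize trilinearly, labels nearest-neighbor.

## Evaluation

Hard Dice `2|X∩Y|/(|X|+|Y|)` per region on argmaxed predictions, with the
community convention both-empty → 1.0 and exactly-one-empty → 0.0. Regions
are the nested label unions ET = {3} ⊆ TC = {1,3} ⊆ WT = {1,2,3}. Cohort
numbers are unweighted subject-wise means (not voxel-pooled); the CSV report
retains per-subject scores so any paired statistic can be computed
downstream.

**Split rule.** Cohorts are partitioned by a seeded permutation with
`n_train = ⌊f_train·n⌋`, `n_val = ⌊f_val·n⌋`, remainder to test — the rule
that reproduces 875/125/250 from 1250 subjects at 70/10/20. An optional
per-subject group tag stratifies the same rule within groups.

## Synthetic phantoms

`liunet.synthetic` generates BraTS-layout subjects: a brain ellipsoid
containing a nested tumor — edema shell (label 2) around a core whose rim
enhances (label 3) and whose interior is necrotic (label 1) — with
per-tissue channel means reproducing the qualitative modality contrast
(FLAIR brightest in edema, T1ce in the enhancing rim, T2 bright across the
tumor, T1 near-uniform) plus Gaussian noise (default sd 10 against tissue
contrasts of ~100, i.e. ~10%). Radius ranges scale with volume size and must
nest strictly; geometry, contrast and noise all derive from
`(seed, subject_index)` so cohorts are bit-reproducible and
order-independent. An option writes the raw enhancing label 4 to exercise
the remap path.

Phantoms deliberately omit MRI texture, bias fields, multifocal lesions,
irregular boundaries and inter-subject anatomy. Tests passing on phantoms
therefore demonstrate that the pipeline is plumbed correctly and that the
network can fit controllable geometry — not that any accuracy level carries
over to clinical data.

## Problem sizes used in tests

The suite exercises the exact BraTS geometry where it is cheap (reading and
resizing a 240×240×155 phantom) and reduced sizes elsewhere, chosen so the
whole suite runs in minutes on one CPU: unit tests use 16³ volumes with a
(4, 8, 16, 32, 32)-width network; the overfit check trains a
(8, 16, 32, 64, 64)-width network on four 32³ phantoms for 150 Adam steps at
lr 5×10⁻³ (chosen from a reference run; the published-scale recipe of
lr 10⁻⁴ / batch 2 / 100 epochs at 128³ remains the config default). That
run reaches mean foreground soft Dice ≥ 0.8 on its training set and beats
the untrained network's whole-tumor hard Dice by a wide margin.

## Known limitations

- Training at full 128³ resolution with the default widths is possible but
  slow in this NumPy engine (~minutes per optimizer step on one CPU); the
  implementation is a verified reference, not a production trainer.
- `device: gpu` is accepted in configs but falls back to CPU with a warning.
- Batch-norm statistics with batch size 2 are noisy; running averages
  (momentum 0.1) need a few dozen steps before inference-mode outputs
  stabilize.
- The published parameter total (≈3.1 M) cannot be matched exactly without
  the original per-level widths; the default schedule matches it in
  magnitude (3.45 M) and the enforced property is only the lightweight bound
  relative to the U-Net baseline.
- No augmentation beyond optional axis flips (off by default); no test-time
  ensembling, patching or post-processing.
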