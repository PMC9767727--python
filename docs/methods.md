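# Methods

## The classification problem

Hepatic steatosis raises the echogenicity of liver parenchyma on B-mode
ultrasound and, when severe, attenuates deep echoes.  Radiologists grade it
into four classes — normal (C1), low (C2), moderate (C3), severe (C4) —
that form two gray-close pairs: C1/C2 dark, C3/C4 bright.  The pipeline
classifies small gray patches cut from a rectangular region of interest
inside the liver, which multiplies the effective sample size of a scarce
annotated dataset and restricts the classifier to parenchymal texture.

## Differential-image augmentation

For each pair {a, b}, let φ be the mean gray value over all pixels of all
patches in the pair and φ_i the per-class mean.  Each patch I_j of class i
yields a differential patch DI_j = I_j − (φ_i − φ).  Two properties matter:

- **Class-mean equalisation.**  E[DI | class] = φ for both classes — an
  algebraic identity, property-tested to 1e-6.  Within a pair the dominant
  brightness cue is removed, so differential patches are classifiable only
  through texture.
- **Leakage control.**  The train/test split is drawn first (stratified by
  class, seeded) and the group statistics and differentials are computed
  from the train side only; a differential whose parent sits in the test
  set raises an error.  Differential values may leave [0, 255] and are kept
  signed, unclipped.

The standalone transformation defaults to converting half of a group's
patches; the split builder converts all train-side patches (fraction 1.0),
which with a 50% train fraction yields the canonical composition of N
original training patches plus N differentials against N held-out originals
(1000 + 1000 / 1000 at 500 patches per class).

The subtraction is read as I_j minus the class offset (φ_i − φ), i.e. a
re-centring onto the common mean.  The alternative left-to-right reading
(I_j − φ_i − φ) would shift every class to a large negative mean and
equalise nothing; it is not implemented.  φ and φ_i are scalars (grand gray
means) by default, matching how per-grade gray statistics are reported; an
opt-in pixel-wise variant replaces them with per-pixel mean images, aligning
every pixel position's class mean with the group's.

## Patch extraction

A w×w window (default 28) slides over the ROI with a configurable stride
(default w/2) in raster order; windows are half-open, [origin, origin + w)
per axis, 0-based.  The per-axis count floor((extent − w)/stride) + 1 is
tested against brute-force origin enumeration.  A per-class cap subsamples
uniformly (seeded) to emulate obtaining a target patch count per grade from
a handful of images.  Patches keep raw 8-bit values; normalisation (divide
by 255, sign preserved for differentials) happens at training time.

## Network and complexity

Reference topology: 28×28×1 → conv 3×3×64 stride 1 pad 1 → ReLU → max-pool
2×2 stride 1 → conv 3×3×198 (unpadded) → ReLU → flatten 123 750 → FC-19200
→ FC-4 → softmax.  The unpadded second convolution is what makes the
flatten 25·25·198 = 123 750 and the totals below self-consistent.

The skip connection ("structure A") max-pools the raw single-channel input
with the same 2×2/stride-1 window and broadcast-adds it across the 64
channels of the pooling layer's output, i.e. at the second convolution's
input.  The addend carries no trainable parameters, so backpropagation
through it is the identity on the main path.  At inference the sample's
class — hence its differential — is unknown, so the addend is always the
network's own current input, pooled; during training, differential patches
are themselves inputs, so the skip carries differential content for exactly
those samples.  Whether the addend should instead enter before the first
ReLU is underdetermined; adding at the pooled output was chosen as the
literal "input of the second convolution".

Complexity is counted symbolically and exactly: conv parameters
k·k·c_in·f + f, FC parameters d_in·d_out + d_out, batch-norm 2·channels;
MACs k·k·c_in per conv output element and d_in·d_out per FC, with biases,
activations, pooling and the skip addition excluded (one MAC = one FLOP).
Under this convention the reference network has 2 376 210 890 parameters
(2376 M, rounding half-up) and 2 447 808 384 MACs (2448 M); the FC layers
hold 99.995% of parameters and 97.07% of MACs.  Counts are verified against
two independent oracles: the number of scalars in an instantiated network
(50 random specs) and a naive triple-loop convolution multiply counter.

### Experiment-scale network

The reference network is an audit target, not a trainable artifact: 2.4e9
parameters occupy ~9.5 GiB in float32 before optimiser state.  All training
experiments therefore use a width-scaled twin with identical layer order
and skip semantics — conv 3×3×16 pad 1 → ReLU → pool 2×2 s1 → conv 3×3×32
→ ReLU → flatten 20 000 → FC-64 → FC-4 (≈1.3 M parameters).  In kernel-size
sweeps, convolutions after the first are padded by (k−3)//2 so every sweep
point keeps the k = 3 output extent: parameter counts then grow
monotonically with k and the sweep compares equal-width classifiers (at
k = 3 the padding is zero, i.e. exactly the reference topology).

## Training

Adam (β₁ 0.9, β₂ 0.999, ε 1e-8) minimises the 4-way cross-entropy at base
learning rate 0.001 with step decay ×0.5 every 5 epochs; defaults 20
epochs, batch 32.  The rate warms up linearly over the first 100 steps:
with Adam's sign-like initial steps and a 20 000-dimensional FC fan-in,
full-rate first steps swing the logits by O(10) and can leave the second
convolution's ReLU permanently dead (all activations negative, zero
gradient, accuracy pinned at chance) — warmup removes that failure mode.
The per-epoch base rate is non-increasing.  All shuffling and
initialisation (He normal, float32) is seeded; two runs with the same seeds
are bit-identical.  A non-finite loss raises an error naming the step.

Evaluation reports the 4×4 confusion matrix (rows true, columns predicted;
argmax ties broken toward the lowest class index), accuracy = trace/total,
and one-vs-rest sensitivity TP/(TP+FN) and specificity TN/(TN+FP)
macro-averaged over the four classes — the natural multiclass extension
when single scalars are wanted.  A zero true-class probability in the
cross-entropy is clamped at 1e-12 with a logged warning.

## Synthetic data: what it emulates and what it does not

Each grade is generated as a recentred Rayleigh speckle field: pixel =
target_mean + (R − E[R]) with R ~ Rayleigh(speckle_scale), Gaussian-smoothed
to the grain size, row-wise attenuated by (1 − rate)^row, rounded and
clipped to 8 bits.  The additive recentring keeps the speckle amplitude
tunable in gray levels and makes the zero-noise limit exactly constant.
Defaults: class means 70/85/150/165 (the two-pair grouping, within-pair gap
≪ between-pair gap), speckle scale 25 gray levels, grain 1.0 px for C1/C3
vs 2.5 px for C2/C4, attenuation 0.002/row for C4 only.  The within-pair
grain difference matters: fat accumulation alters the scatterer population
and hence speckle autocorrelation, and without some non-brightness cue the
differential patches of a pair would be statistically identical yet
differently labeled, which contradicts the premise that gray-close grades
stay separable by pixel-level texture after brightness equalisation.

The generator is a texture emulator, not an acoustic simulation — no
scan-line geometry, TGC, probe model, anatomy, shadowing or patient
variability.  Consequently, passing training checks here shows that the
pipeline, augmentation and optimiser behave correctly on data with the
intended gray-level structure; it says nothing quantitative about clinical
accuracy.

A known ceiling effect follows: the default synthetic task is perfectly
separable, the no-skip structure B reaches 100% test accuracy, and the
skip's common-mode addend adds slight optimisation friction, so structure A
ties or trails by ~1 point in median rather than beating B.  The skip's
documented advantage belongs to hard clinical texture where the baseline is
far from ceiling; demonstrating it would require an emulator of realistic
difficulty, which is out of scope.

## Default experiment conditions

The default synthetic experiment uses 4 images per class at 256×256 (window
28, stride 14, per-class cap 500 patches), the 50% + all-differentials
split, and the experiment-scale network, sized so that a full seeded run
trains in about a minute on one CPU.  Five fixed seeds (0–4) are used for
the multi-seed checks; training for the accuracy-target check stops early
once the per-epoch test accuracy reaches the target, within a 12-epoch cap.

## Known limitations

- No irregular/polygonal ROIs, multi-scale windows, or DICOM ingestion.
- Batch normalisation is available for ablations but off by default (it
  destabilises this shallow network's accuracy trajectory).
- The complexity ledger counts the forward pass only and follows the MAC
  convention above; conventions differ across the literature, and
  third-party architectures are out of scope.
- Max pooling is assumed wherever "pooling" is unqualified, including the
  skip path.
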