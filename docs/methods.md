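# Methods

`pleuraseg` implements anatomically constrained training for pneumothorax
segmentation on 2D chest radiographs. Pneumothorax is air in the pleural
space, so on a frontal radiograph a true lesion can only appear in the
"lung + space" — the lungs plus the pleural band inside the thoracic cavity
and outside the mediastinum. The package injects that prior into segmenter
training as a per-image constraint mask, generated without any extra
annotation on the target data, and evaluates the whole procedure end to end
on synthetic phantoms.

## The model

**Baseline.** A segmenter Y(I; θ) maps a grayscale radiograph (replicated to
three channels) to a probability map, trained by minimising the mean soft
Dice loss over the training set,

    ℓ(Y, S) = 1 − (2 Σ Y⊙S + ε) / (Σ Y + Σ S + ε),    ε = 1e−7,

and binarised at 0.5 at inference.

**Constrained training.** Each training image carries a binary constraint
mask C (1 = admissible lesion region). The loss becomes

    L = mean_i [ ℓ(Y_i, S_i) + λ · P(Y_i, C_i) ],
    P(Y, C) = 1 − Σ(Y⊙C) / (Σ Y + ε),

a soft (probability-mass) version of "fraction of predicted area outside the
constraint". P is differentiable in Y, zero exactly when all predicted mass
is admissible, and 1 when none is. λ is grid-selected from
{0.2, 0.4, 0.6, 0.8, 1.0} by validation mean DSC (ties → smaller λ). Two
deliberate short circuits make the fallback semantics exact: an all-ones C
returns P = 0 with zero gradient (not merely ε-close), and a numerically
empty prediction (Σ Y < ε) also returns 0. The first makes constrained
training with all-ones constraints *bit-identical* to baseline training,
which the test suite asserts.

**Constraint generation (four phases).**

1. *Auxiliary lung segmentation.* A lung-field segmenter is trained on a
   separate clean dataset (standing in for public lung-segmentation
   corpora), with the same Dice objective.
2. *Refinement into lung + space.* Predicted lung masks are refined by
   keeping the top-2 connected components (8-connectivity, ties by earliest
   raster pixel), closing with a 19×19 ellipse element, then dilating with a
   15×15 ellipse element. The element is the discrete filled ellipse
   ((r−m)/m)² + ((c−m)/m)² ≤ 1, m = (size−1)/2. Dilation pads the grid
   conceptually with background; the erosion inside closing is its dual
   (outside counts as foreground), which keeps closing extensive at the
   frame. Cutoff → close → dilate is a fixed order.
3. *Reliability discrimination.* Transferred constraints are noisy under
   domain shift. Each train/validation sample is scored by the coverage rate
   R = |C∩S| / |S| and labelled reliable iff R ≥ τ (τ = 0.99; the boundary
   is non-strict so a constraint covering exactly τ of the lesion is kept).
   A small CNN classifier is trained with cross-entropy on channel-fused
   inputs (I, C, I⊙C). A score cutoff is the smallest point on a
   {0, 0.01, …, 1} grid whose validation specificity reaches a target
   (targets 0.80/0.85/0.90/0.95; 0.90 is used for assembly). Samples at or
   above the cutoff keep their constraint; the rest fall back to all-ones.
   Only train/validation samples enter this phase — the interface does not
   accept the test split, so leakage is structurally impossible.
4. *Constrained segmentation.* The lesion segmenter is retrained with the
   assembled constraints; everything else (architecture, optimiser,
   schedule) matches the baseline run exactly.

## Networks and optimisation

No GPU framework is used: both networks are compact numpy models with
hand-written backpropagation (im2col convolutions, 2×2 average pooling,
nearest-neighbour upsampling, float32 parameters). The segmenter is an
encoder–decoder with skip connections (default depth 2, base width 8,
~9k parameters); the classifier is the same trunk with global average
pooling and a linear head. Gradients of every layer and of both loss terms
are verified against central finite differences in the test suite.

Optimisation is SGD with momentum 0.9, lr₀ = 0.01, lr × 0.9 after 5 epochs
without validation improvement (strict improvement by > 1e−5 of the
monitored score: mean validation DSC for segmenters, negative cross-entropy
for the classifier), early stopping after 15 epochs without improvement,
best-validation weights restored. Inputs in [0, 1] are internally centred to
[−1, 1]; without centring, the all-positive inputs couple first-layer
gradient directions and the tiny net needs several times more epochs to
leave the small-foreground Dice plateau. Batch size 4. Everything is
pure-numpy deterministic given the config seed; every stochastic component
of the pipeline derives its seed from one global seed, so a full re-run
yields byte-identical report CSVs.

## The phantom generator

Each phantom is a square grayscale image (default 64×64; 224 supported)
with four aligned grids: image, lung mask (two elliptical lung fields inside
a brighter thorax ellipse), lung+space mask (lungs dilated by a pleural rim,
default 2 px), and lesion mask. Lesions are lucent (brighter than lung,
texture-suppressed) regions whose area is drawn from 3–10% of the
lung+space; 70% are crescents hugging the pleural margin — the typical
pneumothorax geometry — and the rest blobs. With probability
`lesion_outside_prob` a lesion is deliberately placed outside the
lung+space (used to stress the discriminator; 0 in the standard benchmark).

Two features make the benchmark behave like the intended study regime
rather than a toy exercise:

* **Pneumothorax mimics.** Real radiographs contain lucencies outside the
  lung+space that locally resemble pneumothorax (skin folds, bowel gas).
  Each phantom therefore contains 2–4 mimics: lucent cores inside lung-like
  dark halos, rendered with exactly the lesion's intensity and texture
  statistics, seeded in a ring 6–16 px outside the lung+space. The ring
  starts beyond the reach of the 15×15 dilation so mimics remain
  inadmissible even after constraint refinement — position is the only cue
  separating them from true lesions, which is precisely the ambiguity the
  anatomical constraint resolves.
* **Domain shift.** Target-domain samples are corrupted by gamma
  (0.7–1.4), additive Gaussian noise (σ = 0.05), and small affine warps
  (≤2 px shift, ≤4° rotation) applied jointly to image and masks, emulating
  acquisition differences between the auxiliary and target domains that
  make transferred constraints unreliable. On top of that, the standard
  benchmark heavily degrades a random 30% of transferred constraints
  (erosion radius 8–12 plus 20–28 px shift — severe enough that nearly all
  degraded constraints genuinely lose lesion coverage) so the discriminator
  has a genuine two-class problem.

What the phantoms do **not** emulate: ribs/clavicles, projection physics,
patient habitus variation, annotation noise, or 1024² resolution. Passing
tests therefore demonstrate that the *mechanism* works (constraints are
generated, filtered and exploited correctly, and help when location
ambiguity exists); they say nothing quantitative about clinical data.

## Evaluation

IoU and DSC use the convention that two empty masks score 1 (correct
negatives on lesion-free crops). The Hausdorff distance is the full
symmetric textbook definition in pixel units via an exact Euclidean
distance transform; one empty mask scores the grid diagonal, two empty
masks 0. AUROC is the Mann–Whitney probability with half-credit ties.
Confidence intervals are percentile bootstrap of the mean (1000 resamples,
95%, seeded). Improvement percentages are relative: (ours−base)/base for
IoU/DSC and (base−ours)/base for HD, where lower HD is better.

## Benchmark problem sizes

The standard benchmark uses 64×64 phantoms: 60 auxiliary samples
(70/15/15 split), 180 target samples split 120/20/40 (the 70/10/20
convention), λ = 0.6, 50 training epochs maximum, three seeds for the
ablation (baseline / raw lung constraints / refined constraints / refined +
discriminator). These sizes were chosen so a full ablation runs on one CPU
core in minutes; the mechanisms under test do not depend on scale.

## Numerical choices and edge cases

* ε = 1e−7 in both loss terms guards empty predictions/targets.
* Binarisation threshold 0.5, with ≥ (a uniform 0.5 map is all foreground).
* Coverage is undefined for an empty lesion and raises (target data are
  lesion-positive by construction); an empty refined constraint simply gets
  coverage 0 and is labelled unreliable.
* Cutoff grids are rounded to 10 decimals to avoid float drift; if no grid
  point attains the specificity target the topmost point is returned and
  flagged.
* RLE masks use the SIIM-ACR public convention: column-major flattening,
  1-based starts, "-1" for an empty mask. Mask resizing is
  nearest-neighbour (binarity-preserving); image resizing bilinear.
* Largest-remainder apportionment turns split ratios into integer sizes
  (ties broken toward the earlier split).

## Known limitations

* The compact numpy networks are far smaller than the VGG/U-Net-scale
  models used in clinical studies; absolute metric values on phantoms are
  not comparable to published clinical numbers, and the Hausdorff
  magnitudes depend on the 64×64 grid.
* The discriminator is applied to the same train/validation pool it was
  fitted on when assembling constraints (scores on the training split come
  from the trained model), an optimism the downstream segmenter inherits;
  the test split never participates.
* Robustness sweeps run one seed per grid point to stay desk-scale.
* At desk scale the constrained-vs-baseline overlap difference is small
  relative to seed-to-seed variance; single-seed comparisons can go either
  way, which is why the benchmark protocol reports three-seed means (the
  Hausdorff improvement, driven by pruned out-of-region predictions, is the
  most consistent signal).
* The specificity-cutoff grid search assumes validation labels contain both
  classes; heavily benign constraint pools need `lesion_outside_prob` or
  explicit corruption to exercise it.
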