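# Methods

## Problem setting

`lesionmil` classifies 8-bit grayscale CT-like images of an organ into a
lesion-positive class (focal malignant lesion present) and a non-malignant
class (normal, diffusely rough, or benign-cystic tissue), without any lesion
segmentation.  Supervision is weak: labels attach to whole images.  The
package therefore treats each image as a *bag* of equal square blocks
(*instances*) under the standard multi-instance assumption — a bag is
positive iff at least one of its instances is a lesion block.

## Pipeline

1. **Preprocessing.**  Each frame is resized to 339 × 339 (bilinear, then
   rounding to the nearest integer intensity) and passed through global
   256-bin histogram equalization — a monotone remap
   `round(255 · (cdf − cdf_min) / (1 − cdf_min))` that preserves pixel rank
   order and keeps a constant image constant.  Equalization can be disabled
   per configuration (see Limitations).
2. **Bag construction.**  The frame is partitioned into a k × k grid with
   `k = round(side / block_length)` and boundaries `round(i · side / k)`;
   fractional block lengths (e.g. 169.5 on 339 px) therefore produce
   rounded equal partitions that always cover every pixel exactly once.
   Instances are ordered row-major.  The default block length is 113
   (9 instances per 339 px frame).
3. **Texture features.**  For each instance, co-occurrence matrices are
   accumulated symmetrically at distances d ∈ {1, 2} and directions
   θ ∈ {0°, 45°, 90°, 135°} after quantizing intensities into G = 64
   equal-width bins of [0, 255].  Diagonal offsets step d pixels per axis
   (the classic Haralick convention; the equivalent `skimage` distance is
   d·√2).  From each normalized matrix `I`:

   - ASM = Σ I(i,j)²
   - ENT = −Σ I(i,j)·log₁₀ I(i,j)  (0·log 0 := 0)
   - CON = Σ (i−j)²·I(i,j)
   - COR = [Σ i·j·I(i,j) − μₓμ_y] / (σₓσ_y), with the standard marginal
     moments μₓ = Σᵢ i·pₓ(i), σₓ² = Σᵢ (i−μₓ)²·pₓ(i) over bin indices, and
     COR := 0 when σₓσ_y = 0.

   Per distance, the mean and population variance of each statistic across
   the four directions are emitted: a 16-dimensional instance vector
   (an 8-dimensional distance-pooled variant is available).
4. **First instance optimization.**  A block containing no tissue is a
   single gray level, so its ASM is exactly 1; instances whose mean d=1 ASM
   reaches `1 − asm_tolerance` (default 10⁻⁹) are discarded as background.
5. **Instance scoring and second instance optimization.**  Instances
   inherit their bag's label (±1), which is noisy in positive bags.  Bags
   are dealt into `selection_folds` (default 5) stratified folds; each fold
   is predicted by an RBF-SVM tuned and trained on the other folds'
   instances, so no instance is scored by a model that saw its bag.
   Bags at or above the `excellent_bag_quantile` (default median) of
   per-bag instance accuracy — computed within each class — contribute
   their correctly classified instances to the *key-instance set*, the
   deployable training set.  Members from positive bags carry the flag
   a_j = 1, members from negative bags a_j = 0; by default all key
   instances train the final model (an SVM needs both classes), and a
   `strict_aj_mask` switch restricts the rows to a_j = 1 for the
   alternative reading of the selection flag.
6. **Hyperparameter tuning (PSO + local search).**  The penalty C and RBF
   control factor g are tuned on the key-instance set: global-best particle
   swarm optimization in (log₂ C, log₂ g) over C ∈ [2⁻², 2⁷], g ∈ [2⁻⁴, 2⁴]
   (inertia 0.9 → 0.4, c₁ = c₂ = 2), fitness = mean stratified k-fold CV
   accuracy on fixed folds; then a coordinate line search around the PSO
   optimum — C sweep at fixed g, then g sweep at the kept C, ties resolved
   toward smaller values.  Both sweeps include their start point, so the
   combination never degrades the PSO fitness.
7. **Bag prediction.**  Reserved (non-background) instances of a test bag
   are classified; with r = fraction predicted negative, the bag is
   negative iff r > P (strict), default P = 0.86.  With 9 instances this
   means a bag needs at least two positive-predicted blocks to be called
   positive.
8. **Evaluation.**  ACC/SEN/SPE from the confusion counts with the lesion
   class positive; undefined ratios are reported as absent, never as 0.
   The validation protocol splits each class 50/50 into train/test,
   builds the classifier on the training half, deals the test half into
   five stratified groups, and reports the unweighted mean of the five
   groups' metrics.

## Baselines

- **Whole-image SVM**: one GLCM vector per full frame, same tuning, same
  protocol.
- **Citation-kNN** with the minimum Hausdorff bag distance (smallest
  pairwise instance distance; symmetric, zero on identical bags, *not* a
  metric).  References = R nearest training bags (default 2); citers =
  training bags whose C_cite-nearest neighbourhood among the remaining
  training bags plus the query includes the query (default rank 4, the
  R + 2 convention); majority vote, ties to the non-malignant class.
- **WEMISVM-style**: bags dissolved (instances take bag labels), one tuned
  instance-level SVM, bag label = sign of the mean instance decision value
  (0 → positive).  This is a single-model variant of the original ensemble
  formulation.

## Synthetic phantoms

The generator emulates the study conditions end to end: 512 × 512 8-bit
frames, one mildly eccentric elliptical organ (default 45 % of the frame)
on a uniform zero background, parenchyma texture = white Gaussian noise
smoothed at a correlation length of 6 px, scaled to mean 120 / SD 20.
Classes:

- *normal*: texture only;
- *cancer* (bag label +1): 2–4 irregular focal lesions (unions of 3–7
  jittered disks, radii 45–70 px) at intensity offset −60 with its own
  texture (SD 12);
- *cirrhosis*: no focal lesion, rougher parenchyma (SD 38, correlation
  length 1.8 px);
- *cyst*: one sharply bounded homogeneous disk (offset −90, SD 1.5).

Lesion radii are sized so a typical positive bag has 2–6 lesion-bearing
blocks at block length 113 — necessary for the threshold rule, since a
single positive block out of nine gives r = 8/9 > 0.86 and would be called
negative.  Ground-truth lesion masks are emitted for every sample.
Everything is a deterministic function of (config, seed); datasets derive
per-sample seeds from one master seed.

What the phantoms do **not** emulate: anatomy, Hounsfield physics, partial
volume, acquisition noise, patient-to-patient variation in organ shape and
global intensity, and co-registration artifacts.  Passing tests on
phantoms demonstrate the pipeline's mechanics (background removal, key
instance selection, threshold behavior, tuning contracts), not clinical
performance.

## Numerical and design choices

- **Quantization**: G = 64 equal-width bins balances texture resolution
  against sparse-count noise for ~113 × 113 blocks; entropy uses log₁₀
  (configurable) — the base only rescales one feature, which the tuned
  kernel absorbs.
- **Correlation marginals** use the standard matrix-marginal moments; the
  degenerate single-level case returns COR = 0.
- **Feature standardization**: features are z-scored (statistics from the
  training rows only) in front of the RBF kernel, inside both the final
  fit and every CV fitness fold.  The raw statistics span about four
  orders of magnitude (ASM ≤ 1 vs contrast in the thousands), and a shared
  kernel width over unscaled axes collapses the classifier onto the
  majority class.
- **Per-class excellent-bag quantile**: positive bags carry mostly
  non-lesion blocks with borrowed positive labels, capping their
  attainable per-bag accuracy well below negative bags'; a pooled quantile
  therefore tends to exclude every positive bag and leave the training set
  single-class.  Applying the quantile within each class keeps both
  classes while preserving the monotonicity of the selection in the
  quantile.
- **Degenerate-input handling**: CV fold counts are clamped to the
  minority-class count; if a class ends with fewer than two key-instance
  rows the tuner falls back to box-center parameters; and if a class
  contributes no correctly classified instance at all (possible under
  heavy label noise), its best-scoring bag is retained wholesale so the
  final training set always covers both classes.
- **Tie rules**, all documented in code: decision value 0 → +1; bag ratio
  exactly P → positive; line-search ties → smaller C, then smaller g;
  Citation-kNN vote ties → negative; citation rank ties favour citing.
- **Problem sizes**: full pipeline runs in the test suite use 10–24 bags
  with a 6-particle × 8-iteration swarm and a coarser line search
  (steps 0.25, half-widths 1.0/2.0); the end-to-end recovery check runs
  the 80 + 120-bag design with the pipeline default budget (10 × 12 swarm,
  3-fold fitness, line-search steps 0.05).  The stand-alone tuner defaults
  are 20 particles × 50 iterations with 5-fold fitness.

## Limitations

- **Global equalization leaks bag identity on these phantoms.**  Because
  all phantom classes share identical parenchyma statistics, a lesion's
  footprint in the global histogram changes the equalization remap of
  *every* block in that image; an instance classifier can then recognize
  even lesion-free blocks of positive bags, which voids the
  lesion-vs-other selection contrast (measured selection rates ≈ 0.83 vs
  0.96 with equalization, 0.97 vs 0.07 without).  Real images differ
  globally for many patient-specific reasons, so this is a phantom
  artifact; the key-instance enrichment check therefore runs with
  equalization disabled, while equalization remains the pipeline default.
- The minimum Hausdorff bag distance violates the triangle inequality;
  Citation-kNN results depend on R and C_cite, for which no principled
  defaults exist beyond convention.
- Only binary tasks are supported; multi-class discrimination is out of
  scope.
- Timing figures are hardware-dependent and are reported but never
  asserted.
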