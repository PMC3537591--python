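# Methods

This note records the models and procedures implemented in `mammocalc`,
the parameter choices that matter, and what the synthetic benchmarks do
and do not demonstrate.

## Dual-tree complex wavelet transform

The transform runs two parallel real discrete wavelet trees; tree A
supplies the real and tree B the imaginary part of each complex
coefficient, so the effective wavelet is ψ = ψᵣ + jψᵢ with (ψᵣ, ψᵢ)
approximately a Hilbert pair. Analyticity requires the two trees' low-pass
chains to stay half a sample apart at every scale:

* **First stage** — both trees share one symmetric biorthogonal pair, the
  CDF 9/7 (`bior4.4` in PyWavelets), and tree B is offset by one input
  sample. The offset is realized as a circular shift of the signal before
  filtering, which is exactly invertible and keeps the two trees' sub-band
  grids congruent. The CDF 9/7 was chosen over shorter spline pairs
  (LeGall 5/3) because the 5/3 analysis low-pass has nearly unit gain at
  0.64π; that stop-band leakage destroys the ± orientation separation of
  the 2-D transform (measured during development with oriented gratings).
* **Later stages** — a 14-tap orthonormal low-pass with quarter-sample
  group delay (energy-centroid delay 6.2493 ≈ 6.25 taps); tree B runs its
  time reverse, giving the half-sample inter-tree delay. The coefficient
  table ships in `src/mammocalc/data/qshift_14.json`. It was produced by
  projecting a published Kingsbury-style q-shift prototype onto the exact
  constraint manifold (double-shift orthonormality, sum √2, zero gain at
  Nyquist) by Gauss–Newton iteration; the projection moves no tap by more
  than ~1.2·10⁻⁷ and brings the perfect-reconstruction residual to
  < 5·10⁻¹⁶ (`scripts/design_qshift_filter.py` regenerates it). The
  filter source is configurable, so alternative published tables can be
  dropped in; any table is validated at load time against the same
  invariants.

Each individual tree is a perfect-reconstruction filter bank, so the
inverse transform inverts every tree and averages; round-trip error is
~10⁻¹² in practice against the contractual 10⁻⁶. Boundary handling is
symmetric (reflect) extension throughout; odd lengths are handled by the
underlying `pywt.dwt`/`idwt` machinery with recorded shapes cropped on
inversion. In 2-D, four parallel separable transforms (row tree × column
tree) are combined by the unitary sum/difference pairing
`c± = ((aa ∓ bb) + j(ba ± ab))/2` into six oriented complex sub-bands per
level. Orientation labels (±15°, ±45°, ±75°) are nominal: the band labeled
+45° is, by construction and by test, the band that responds maximally to
a +45° grating. A one-pixel shift changes per-sub-band magnitude energies
by far less than for a critically sampled DB4 DWT on the same image (at a
one-sample 1-D shift, level-1 magnitude energy is exactly invariant, since
the shift swaps the roles of the two trees).

## Detection

Both branches operate on the gray-normalized ROI (normalization precedes
everything else in the pipeline order). The spatial branch computes
f₁ = ROI − ∇²ROI (4-neighbor Laplacian; 8-neighbor by config),
f₂ = 3×3 box mean, f₃ = f₁ − f₂, then the Kirsch compass maximum over the
eight ±5/−3 masks, thresholded at the 97th percentile by default. The
wavelet branch zeroes the level-1 details and the entire level 4
(approximation + details) of a 4-level DB4 decomposition — level 1 carries
mostly noise and level 4 mostly background — and thresholds the
reconstruction at the 98.5th percentile. Percentile thresholding is the
default for **both** branches: Otsu on the band-pass magnitude tracks the
noise/texture split rather than a fixed false-positive budget, and
measured strictly worse sensitivity at matched FP/image on a held-out
synthetic set (0.63 @ 4.75 FP/img vs 0.81 @ 2.7); Otsu remains available
via `DetectionConfig(wavelet_method="otsu")` and is the method used by
`binarize` when asked. A branch image with zero dynamic range (e.g. a
blank ROI) contributes an empty mask — "no evidence" — rather than the
all-foreground mask a literal ≥-threshold rule would produce.

Spots are 8-connected components of the fused (AND) mask with at least
`min_spot_px = 2` pixels. Per spot: centroid, boundary-weighted area
(interior pixels 1.0, boundary pixels 0.5 — compensating the discrete
sampling of a continuous object), and Euler number E = C − H with
8-connected foreground and 4-connected holes (the standard consistent
digital-topology pairing).

## Features

The 14-vector is [m₂, m₄, T₁..T₉, W₁, W₂, W₃].

* Histogram moments use 256 levels and raw counts with a leading 1/N, i.e.
  the standard central moments (variance, fourth moment) of the gray
  histogram. The third moment is implemented but excluded from the
  14-vector.
* GLCMs quantize the ROI's own intensity range to K = 16 levels
  (identical to quantizing [0, 255] for normalized input), accumulate
  symmetric counts at distance 1 over angles {0°, 45°, 90°, 135°}, and
  normalize to sum 1. T₁..T₉ use natural logarithms; 0·log 0 := 0; the
  correlation T₅ falls back to 0 with a warning when a marginal is
  degenerate.
* Wavelet features summarize the 12 sub-bands of a 2-level DT-CWT by mean
  magnitude energy e_s: W₁ = Σe_s, W₂ = level-1/level-2 energy ratio, and
  W₃ = entropy of the normalized energy distribution (maximal ln 12 for
  equal energies, defined 0 for an all-zero pyramid). These three
  summaries are rotation-robust and scale-aware; per-level energies are
  available by config.
* Spot-level area and Euler number are detection outputs, not part of the
  14-vector.

## Classification

Features are z-scored and the correlation matrix eigendecomposed; the top
4 components are kept (fixed retention, mirroring the study design; a
variance-threshold mode exists but is off by default), with a
deterministic sign convention (largest-magnitude loading positive). The
comprehensive score is the explained-variance-weighted sum of the four
component scores; it is used for visualization and available as the SVM
input by config, but the SVM consumes the four scores by default. Inside
the SVM the component scores are standardized per fold: score variances
are proportional to their eigenvalues, and an unscaled polynomial kernel
would let the first component swamp the rest (this raised stage-2 LOOCV
from ≈0.55 to ≈0.8 on synthetic data).

The SVM is a soft-margin polynomial machine, kernel (γ·xᵀx′ + 1)^d with
γ = 1/n_features and C = 1 (standard defaults; the pipeline's contribution
is the feature chain, not SVM tuning). Stage 1 (normal vs abnormal) uses
d = 2, stage 2 (benign vs malignant) d = 3; both configurable. LOOCV
refits standardization, PCA and the SVM inside every fold, so the held-out
sample never touches the fold's model; accuracy is the exact ratio
correct/n.

## Evaluation

ROC is computed on the stage-1 LOOCV decision values (negated so larger
means more abnormal), with tie-grouped thresholds and trapezoidal AUC —
identical to the Mann–Whitney pair-counting statistic. FROC sweeps the
spatial-branch percentile (the most sensitivity-controlling stage;
configurable to the wavelet branch), pooling TP/FP over the dataset.
Matching is greedy nearest-first and one-to-one: a spot matches an
unclaimed truth within max(truth radius, 5 px). Greedy matching is maximal
but not always cardinality-optimal; on random small instances it stays
within the brute-force optimum's factor guaranteed for maximal matchings
(tests exercise this bound).

## Synthetic data

The generator emulates what the detector and classifier need from real
mammographic ROIs — not X-ray physics. Backgrounds are a mean level of 120
plus three seeded components: a broad smooth random field (Gaussian-kernel
σ = 16 px) range-scaled to 80 gray levels, mid-frequency texture (σ = 2 px)
range-scaled to 15, and white noise of σ = 4. Range scaling (rather than
scaling the field's standard deviation) keeps the realized dynamic range —
and hence the gray-normalization stretch — stable across ROIs of a class;
with SD scaling the stretch factor varied so much within class that it
masked the lesion signal entirely.

Benign lesions are round soft Gaussian spots (σ = 0.6·radius, radius
U(2,4) px, contrast U(40,70)) scattered with ≥ 12 px pairwise separation.
Malignant lesions are clusters (centers inside a 20 px disk) of
fine-pleomorphic spots: each is the union (pointwise max) of 2–4 sharply
marginated quasi-disk lobes (profile exp(−u³) of the squared Gaussian
argument, lobe σ ∈ U(1.0, 1.5)·radius/2, jitter σ = radius, full contrast
per lobe; radius U(1,5), contrast U(30,80)). The benign/malignant split
thus encodes the BI-RADS-style morphology distinction — coarse smooth
round scattered vs fine sharp irregular clustered — in a form that global
texture descriptors can sense. Malignant ground truth records the realized
lobe centroid and spread rather than the nominal draw centre, since the
jittered lobes are the object actually planted. Abnormal ROIs carry 4–12
spots; every draw flows from one seeded generator per ROI (seed + index),
so datasets regenerate bit-identically.

**What passing benchmarks show — and don't.** On the default 50-ROI study
the two-stage classifier reaches ≥ 0.9 (stage 1) and ≥ 0.8 (stage 2)
LOOCV accuracy, and the detector reaches ≥ 0.8 lesion sensitivity within
3 FP/image on a 20-image set. These verify that the implemented chain
extracts and uses the morphology signal the generator plants. They do not
predict clinical performance: real parenchyma is non-stationary and
non-Gaussian, real calcifications are not additive Gaussian/disk profiles,
and ROI selection in a clinical study is itself informative. Stage-2
accuracy fluctuates by roughly ±0.1 across dataset seeds at n = 25 — a few
draws are genuinely ambiguous (e.g. malignant clusters realized with few,
small spots) — so single-seed stage-2 readings below 0.8 occur.

## Numerical and degenerate-input conventions

Constant images are rejected by gray normalization and Otsu (zero dynamic
range); empty masks are rejected by the weighted area but give Euler
number 0; an all-zero pyramid yields wavelet features (0, 0, 0). The q-shift
table is validated at import (PR on an impulse < 10⁻⁸, sums, zero mean,
half-sample delay within 0.1). Percentile thresholds use NumPy's linear
interpolation; ROC ties share a threshold step; LOOCV accuracy is an exact
integer ratio. Problem sizes in the test suite (128×128 ROIs, 50-ROI
studies, 20-image FROC sets, 100-image reconstruction sweeps) match the
emulated study design while keeping the full suite under a minute.

## Known limitations

* The q-shift analyticity is that of the packaged 14-tap prototype
  (negative-frequency leakage ≈ 2.7% in energy); longer published tables
  would improve it and can be swapped in.
* Greedy FROC matching can under-count TPs when detections merge in dense
  clusters; cluster-level (rather than spot-level) scoring is out of scope.
* GLCMs are computed over the whole ROI; lesion-neighborhood GLCMs would
  likely sharpen stage-2 but are a different design.
* The CLI's PGM round trip quantizes synthetic images to 8 bits, so
  disk-mediated results can differ in the last decimal from in-memory runs.
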