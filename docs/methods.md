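# Methods

## The problem and the pipeline

Protein spots on a 2-DE gel are dark, roughly Gaussian blobs on a light,
noisy background; the noise class covers plain background, staining
smudges and crack-like artifacts. The pipeline has four phases: (1) data
extraction — labelled ROIs from gel images; (2) pre-processing — texture
features per ROI, z-scored; (3) learning — a panel of classifiers on
shared cross-validation folds; (4) model selection — a nonparametric
statistical workflow that declares a winner.

## Synthetic gel model (`gelsim`)

The simulator emulates the study design rather than electrophoresis
physics. An image is

- a constant light background (default grey 220 of 255) plus an optional
  low-frequency cosine shading field (amplitude 6) and i.i.d. Gaussian
  pixel noise (sd 8);
- crack artifacts: 1–3 px wide dark line segments (depth 60–120 grey) at
  random orientation;
- elevated-noise patches (sd 20) emulating non-protein smudges;
- spots: truncated anisotropic Gaussian *darkening* profiles, depth
  (amplitude) 15–180 grey, σ 3–8 px, with an optional downward tail
  (σ_down = σ·(1+τ), τ ≤ 0.8) emulating streaking. The rendered support is
  the set of pixels darkened by ≥ 1 grey level.

ROIs: a spot ROI is the spot's support dilated by ~20% of its radius
("slightly bigger than the visible dark surface"), padded to a 16 px
minimum side so every feature family is computable; a noise ROI is a
16–40 px rectangle drawn from a background/patch/crack mixture
(0.4/0.3/0.3 by largest-remainder allocation) that never overlaps any spot
support. Noise ROIs are kept pairwise disjoint while space allows;
when short cracks cannot host their quota of disjoint rectangles the
sampler tolerates partial overlap (≤ half the area) late in its retry
budget rather than failing. Spots keep a noise-ROI-sized margin away from
cracks and patches so the designed noise ROIs remain placeable.

The default design is 10 images of 1024×1024 with 50 spot + 50 noise ROIs
each — 1000 ROIs, balanced classes. One integer seed drives a hierarchical
per-image substream (`numpy SeedSequence.spawn`), so any single image is
reproducible independently of the rest. Coordinates are 0-based row-major;
bounding boxes are half-open.

## Texture features (`textures`)

274 features in six families, Mazda-style names. Conventions that had to
be fixed somewhere:

- **Quantization** for GLCM/RLM: Ng = 64 grey levels, full-range window by
  default (`level = floor((g − lo)·Ng/(hi − lo + 1)) + 1`); three-sigma and
  1–99-percentile windows are selectable. Degenerate windows fall back to
  full-range with a warning.
- **Histogram** (9): population moments of in-mask grey levels; kurtosis
  as excess; zero-variance ROIs give skewness = kurtosis = 0; percentiles
  by nearest rank (integer grey levels, no interpolation ambiguity).
- **Gradient** (5): magnitude √(Δx²+Δy²) of unscaled central differences
  over interior pixels (all four neighbours in-mask); `GrNonZeros` is the
  fraction of interior pixels with nonzero magnitude.
- **GLCM** (220): symmetric co-occurrence counts over pairs with both
  endpoints in-mask, normalized to sum 1; 11 Haralick statistics at the 20
  offsets d ∈ 1..5 × {0°, 45°, 90°, 135°}, named `S(dx,dy)Feat`
  (`S(4,0)`, `S(0,5)`, `S(5,-5)` …). Entropies use the natural log with
  0·log 0 := 0. `InvDfMom = Σ p(i,j)/(1+(i−j)²)` is 1 exactly iff p is
  diagonal.
- **Run-length** (20): Galloway SRE/LRE/GLN/RLN/Fraction per direction
  (H, V, 45°, 135°), runs taken along maximal in-mask segments.
- **Autoregressive** (5): zero-mean intensity regressed on W/N/NW/NE
  neighbours by least squares; σ is the population residual sd;
  rank-deficient designs (constant ROIs) return all-zero parameters.
- **Wavelet** (15): orthonormal Haar decomposition of the bounding-box
  crop with mask holes filled by the in-mask mean; energy = mean squared
  coefficient per subband; `periodization` padding for odd sizes. The
  inventory keeps LH/HL/HH at scales 1–4 and LL at scales 1–3 only: the
  deepest approximation band is dominated by mean intensity, which the
  histogram family already measures, and the six family sizes must total
  274.

AR and wavelet operate on the mean-filled bounding-box crop because both
need a regular grid; everything else uses strictly in-mask elements. The
feature extractor is label-blind.

## Standardization (`dataset`)

Features are z-scored. The default is **global** scaling (the whole table
at once, before the CV split), treating the assembled dataset as a unit;
a **per-fold** mode (fit on
training rows, apply to test rows) is provided because global scaling
leaks test statistics — the choice is explicit, not silent. Zero-variance
columns map to 0 with a warning.

## FSMKL (`fsmkl`)

For each texture family the features are ranked by |point-biserial
correlation| with the label (the simplest reading of "statistically
aligned with the class"; ties keep inventory order). The kernel bank is
the product

    {group} × {ranking prefixes of size 1, 2, 3, 5, 8, 13, all}
            × {polynomial-1, polynomial-2, gaussian(γ ∈ {0.01, 0.1, 1}/p)}

with p the prefix size; prefixes are capped at the group size and
deduplicated, giving 175 kernels for the default six groups. Every Gram
matrix is normalized to unit mean diagonal so simplex weights of
heterogeneous families are commensurable; the constants are reused for
test kernels.

Training is SimpleMKL-style alternating optimization: solve the SVM dual
on K(d) (libsvm via scikit-learn, precomputed kernel), take a
reduced-gradient step for d on the probability simplex
(∂J/∂dₘ = −½ βᵀKₘβ) with a backtracking line search that only accepts
non-increasing dual objectives, and stop when max|Δd| < 10⁻³ (at most 60
outer iterations; non-convergence returns the best iterate, flagged).
Weights below 10⁻⁴ are clamped to zero and the rest renormalized before a
final refit — this reproduces "low number of kernels" reporting without
materially changing the optimum. The importance report lists kernels by
weight with cumulative share and rolls importance up to features both raw
(sum of weights over kernels containing the feature, the scale on which a
feature in many kernels can exceed 1) and simplex-normalized; selected
features are the union over non-zero kernels.

C defaults to 10. An inner 5-fold AUROC grid over {0.1, 1, 10, 100}
(`C="grid"`) is implemented but not the experiment default: it multiplies
the number of full MKL trainings per outer fold by ~20 for no visible gain
on the synthetic benchmark.

## Baselines (`baselines`)

- Gaussian naive Bayes (per-class Gaussians, conditional independence).
- RBF SVM with an inner-CV grid over (C, γ) by AUROC.
- Group-MKL: the FSMKL trainer on one kernel per (group × family) with the
  whole group as subset — reports the dominant texture group.
- SVM-RFE: iterative elimination by smallest wᵢ² of a linear SVM, 10% of
  the remaining features per step, one-at-a-time below 30; the retained
  depth maximizes inner-CV AUROC; a guard always leaves ≥ 1 feature.
- GA and binary PSO wrappers over feature masks, fitness = inner-CV AUROC
  of an RBF SVM on the masked columns (memoized per mask). GA: uniform
  crossover 0.8, bit-flip mutation 1/p, tournament selection, elitism 1;
  defaults population 50 × 100 generations. PSO: sigmoid velocity
  thresholding (binary SPSO style), inertia 0.9, c₁ = c₂ = 2, v_max = 4;
  defaults 40 × 100. Zero-feature candidates are repaired by setting one
  random bit. All searches are seed-reproducible and their best-so-far
  fitness traces are non-decreasing.

## Evaluation and model selection (`evaluation`, `statcompare`)

One stratified 10-fold split (seeded reshuffle) is shared by all models of
an experiment — the blocking requirement for the Friedman test. AUROC uses
the rank (Mann-Whitney) tie convention; precision/recall/F are taken at
decision threshold 0 on signed scores (0.5 on posteriors), with zero
predicted positives giving precision 0. Mean ROC curves are vertical
averages on a 101-point FPR grid.

The selection workflow: Shapiro-Wilk (Royston AS R94) and Bartlett checks
motivate the nonparametric route; Friedman average ranks (rank 1 = best,
ties averaged) give χ²_F = 12n/(k(k+1))·[ΣRⱼ² − k(k+1)²/4] and the
Iman-Davenport F = (n−1)χ²_F/(n(k−1) − χ²_F) with df (k−1, (k−1)(n−1));
a perfect ordering makes the denominator zero and is reported as an
infinite F with a flag. The Finner step-down compares everyone to the
top-ranked control via z = (Rᵢ−R_c)/√(k(k+1)/6n), two-sided normal raw
p-values, critical scores cᵢ = 1−(1−α)^{i/(k−1)} and adjusted
p̃₍ⱼ₎ = max_{i≤j}[1−(1−p₍ᵢ₎)^{(k−1)/i}], with tied raw p sharing the
smaller index (this is what makes two identical raw p-values adjust to
the same value). If competitors are not separated, a pairwise Wilcoxon
signed-rank test on per-fold selected-feature counts breaks the tie in
favour of the leaner model (exact distribution for n ≤ 25 without ties,
tie-corrected normal approximation otherwise; all-zero differences give
p = 1, flagged). An exact permutation p for the Friedman statistic is
available for tiny matrices (enumeration over (k!)ⁿ rank configurations).

## Problem sizes and what the tests show

The default `ExperimentConfig` scales the study design down — 10 images at
512×512 with 15+15 ROIs (n = 300) and reduced wrapper budgets
(population 24 × 20 iterations) — so a complete 7-model comparison runs in
a few minutes on one CPU; the simulator's own default keeps the full
1000-ROI design. On these synthetic gels the spot/noise contrast is
stronger than in real silver-stained images: all models reach AUROC ≈ 1.0,
the Friedman omnibus is degenerate by construction, and the workflow
exercises its feature-count tie-break. Passing tests therefore demonstrate
the correctness of the feature definitions, the optimizer and the
statistical machinery — not that real 2-DE classification is this easy.
Features are validated against independent brute-force oracles (explicit
pixel loops, normal equations, exhaustive enumerations) to 10⁻⁹ relative;
FSMKL on a one-kernel bank is validated against a plain SVM to 10⁻⁶.

## Known limitations

- No spot overlap resolution, registration or staining chemistry in the
  simulator; noise ROIs are rectangles while spot ROIs are irregular, so a
  classifier may partly key on mask geometry (as human-drawn ROIs also
  allow).
- The exact composition of the reference 274-feature inventory and the
  reference 546-kernel bank are configuration-dependent; this package's
  defaults are documented above and config-exposed rather than claimed
  identical.
- Global z-scoring (the default, matching the reference) leaks test-fold
  statistics; use `standardize(..., mode="per-fold")` for leakage-free
  estimates.
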