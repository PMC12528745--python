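# Methods

This note records the model as implemented, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical decisions a maintainer would otherwise have to reverse-engineer
from the code.

## Fuzzy kernel generation

A filter is the gene `(w, code)`, both dimensionless in [0, 1] and
clamped on construction. For an `n`-element kernel the position universe
is `p_i = (i + 0.5)/n` (half-offset so the endpoints never sit exactly on
the Low/High peaks). Each `p_i` enters a 9-rule interval type-2
Takagi–Sugeno system as `Numin` together with the gene's `code`:

- **Terms.** Low/Mid/High triangles peak at 0, 0.5, 1 with base
  halfwidth h = 0.5; the footprint of uncertainty perturbs the support by
  δ = 0.1 (upper halfwidth h+δ, lower h−δ). This guarantees full overlap
  of adjacent terms — no input can fail to fire — and non-degenerate IT2
  intervals everywhere except the peaks.
- **Rules.** The 9 antecedent pairs are exactly {Low, Mid, High}²; the
  consequent layout maps them onto {L, M, H} with singleton values
  {0.25, 0.50, 0.75}. Note the layout is *asymmetric* (four H, three L,
  two M consequents), so the inference surface is not mirror-symmetric
  about (0.5, 0.5): the central value is 0.5125, not 0.50. Tests pin this
  against an independent rule-by-rule oracle.
- **Type reduction.** Nie–Tan closed form: firing interval
  [f̲, f̄] by min t-norm, crisp output Σ((f̲+f̄)/2)·y / Σ((f̲+f̄)/2).
  Chosen over Karnik–Mendel iteration because it is deterministic,
  testable in one expression, and has no convergence loop.
- **Dispersion.** `W_i = 3·cos(π·w·Win_i)`. With consequents interior to
  (0, 1), `w` sweeps less than a full cosine period, so kernels stay
  sign-diverse without aliasing. `w = 0` degenerates to the all-3.0
  smoothing kernel; `w → 1` produces mixed-sign, edge-sensitive kernels.

Consequences: every coefficient obeys |W_i| ≤ 3; the generator is
bitwise-deterministic; a filter costs 2 trainable scalars regardless of
kernel size (92.6 % reduction at 3×3×3). A kernel is replicated across
its filter's input channels — that keeps the count at 2 per filter and
makes the forward pass cheap (below).

## Feature extractor

Five same-padded true-convolution layers (scipy.ndimage semantics,
zero-padded borders), channels 8/16/32/64/128, 3×3×3 kernels, no biases.
Activation is `max(0, c·x)` with one slope `c ∈ (0, 2]` per layer (the
affine terms of the general form are frozen at zero). Max pool stride 2
after layers 1–4, replicate-padding odd dims to even first so the spatial
ledger halves exactly; a global average pool after layer 5 gives the
128-vector independent of input size (inputs must be ≥ 16 voxels per
axis to survive four halvings).

Because kernels are replicated across input channels, convolution
commutes with the channel sum: each layer consumes only the *sum* of its
input channels. The implementation propagates that sum and deduplicates
identical kernels within a layer, which makes layer-tied mode (all
filters of a layer share one gene) cost one convolution per layer. This
is an exact algebraic rewrite, verified in tests against the naive
per-channel path and a brute-force triple-loop convolution oracle.

## Optimizers

All three are bounded-box minimizers with one seeded generator per run,
post-move clamping, elitism, and exact budget accounting
(`pop × (1 + iterations)` evaluations).

- **PSO**: inertia 0.729, cognitive = social = 1.49445 (the standard
  constriction-equivalent constants), velocity clamped to half the box
  range. Cold starts draw random velocities; warm starts (the hybrid
  hand-off) start at zero velocity — random momentum at half the box
  range would eject a refined swarm from its basin.
- **TSO** (transit-search-style explorer): per candidate and iteration,
  one proposal from (i) a transit move toward the global best plus
  heavy-tailed Cauchy noise (scale 0.1 × range), (ii) per-coordinate
  recombination with a random other candidate, or (iii) a Gaussian
  perturbation of the best with radius 0.3 × range shrinking by 0.95 per
  iteration; phase probabilities 0.4/0.3/0.3. Proposals are accepted
  greedily. This scheme is the package's own documented explorer; its
  contract is behavioral (bounds, elitism, budget, dominance over random
  search), not a formula reproduction.
- **Hybrid**: TSO for `round(split × iterations)` iterations (default
  split 0.5), then PSO seeded with the TSO population, best candidate
  preserved, so the final best can never regress across the hand-off.
  `split = 1` reduces exactly to TSO.

On the 10-D sphere with a 2000-evaluation budget the hybrid reaches a
median final fitness of ~5e-4 over 10 seeds.

## Two-stage training

Stage 1 draws a stratified, seeded subset (default 100 cases, capped at
the training-split size), and optimizes the concatenated genes plus the
five ReLU slopes — 15 dimensions in layer-tied mode, 2·248 + 5 untied —
with the hybrid (default population 16, 50 iterations). The objective is
the negative **Fisher trace ratio** trace(S_b)/(trace(S_w) + 1e−9) of
the extracted features, with class-count-weighted between-class scatter:
deterministic, head-free, and cheap per evaluation.

Stage 2 freezes the extractor (enforced by hashing the parameters before
and after) and trains the head on the full training features. Features
are standardized with train-set mean/std stored in the model: five
layers of |W| ≤ 3 kernels give activations whose scale varies by orders
of magnitude across genes, and no fixed weight box could serve softmax
otherwise. The FC+softmax head is a 258-dimensional hybrid-optimizer
search in [−2, 2] minimizing mean cross-entropy; the SVM head refines
hinge loss + L2 (λ = 1e−3) by deterministic full-batch subgradient
descent (500 epochs, lr 1/(1+0.05·epoch)) warm-started from the FC
weight difference vector. Decision ties (score exactly 0) go to LGG.

The audited ledger for the desk default is 2×5 + 5 + 258 = 273 scalars
(untied: 2×248 + 5 + head).

## Synthetic cohorts

The generator emulates the study conditions: 230 HGG + 70 LGG with
train/val/test splits (172, 32, 26)/(48, 8, 14); `CohortSpec.desk()` is
the scaled-down preset used by the end-to-end tests — 70 HGG + 30 LGG at
32×32×16 (80 train / 20 test), preserving the ~3:1 imbalance so a full
two-stage run takes minutes on one CPU.

Each case is an ellipsoidal brain (semi-axes ~0.42/0.42/0.40 of the
volume, ±5 % jitter) with smooth Gaussian-filtered tissue texture, and
an ellipsoidal lesion placed wholly inside the brain whose radius is a
fraction of the volume's short axis: 0.18–0.28 (HGG) vs 0.08–0.14 (LGG).
Channel contrasts: T1 hypointense lesion (−0.12), T2/FLAIR hyperintense
(+0.25; FLAIR +0.35 for HGG), and — HGG only — a bright T1ce rim
(+0.5 after the [0,1] normalization scale) and multiplicative core
speckle (σ = 0.3). All channels receive Rician-like noise (magnitude of
a complex Gaussian, σ = 0.05), matching MRI magnitude statistics. The
class signal is therefore carried by lesion size, rim enhancement, and
heterogeneity — the contrasts the classifier is supposed to detect — and
a sanity test checks that hand-crafted-feature separability grows
monotonically with the rim contrast.

What the generator does **not** emulate: bias fields, motion and
ghosting, multi-site intensity shifts, anatomy beyond a single ellipsoid,
infiltrative lesion margins, or multi-focal disease. Passing the
end-to-end tests therefore shows the pipeline recovers the *designed*
class structure at desk scale; it says nothing about accuracy on real
BraTS volumes, and the study's headline numbers are out of reach without
that data.

## Preprocessing and segmentation

The chain is mask → normalize → resample → equalize. The skull mask
(Otsu, largest 26-connected component, closing radius 2, hole fill) is
computed on T1 and shared across the co-registered modalities. Min–max
scaling uses brain voxels only; background stays exactly 0; a constant
brain channel maps to zeros with a warning instead of failing. Only the
in-plane axes are resampled (trilinear) to the target (default 128,
tests use 32); depth is never touched. Equalization is global, 256 bins,
brain voxels only, rank-preserving.

Segmentation runs 3-cluster fuzzy c-means (fuzzifier 2, tolerance 1e−5,
≤ 200 iterations, centers initialized at jittered seeded quantiles) on
the brain voxels of the contrast-like channel, takes the highest-center
cluster, then opening (r=1) → closing (r=2) → largest component → hole
fill. It must be fed the *normalization-stage* output
(`PreprocessConfig(equalize=False)`): equalization flattens the brain
histogram toward uniform ranks and erases the intensity gap the
clustering exploits (Dice on bright-lesion phantoms drops from ~1.0 to
~0.25 with equalized input). Both-empty Dice is defined as 1.0.

## Evaluation

Confusion counts with HGG positive; zero-denominator metrics surface as
explicit `None`, never silent zeros. MAE and RMSE use the standard
definitions (mean absolute, root mean squared error of probability
scores against binary truth) — some printed sources drop the absolute
value or the square; we do not. ROC-AUC is a threshold sweep with
trapezoidal integration, internally cross-checked to 1e−12 against the
Mann–Whitney rank-sum form (ties get half credit). K-fold
cross-validation is stratified and seeded and runs the full two-stage
protocol per fold; K above the minority-class count is rejected.

## Problem sizes used by the test suite

Unit tests run on 16³ volumes and a 20-case mini cohort; the end-to-end
recovery test uses the 100-case desk cohort at 32×32×16 with the default
stage-1 budget (subset capped at 80, 50 hybrid iterations, population
16), sharing stage 1 across the two heads since stage 2 freezes it. The
full suite completes in under two minutes on one CPU core; BraTS-scale
inputs (128×128×N, untied genes) are reachable through configuration
only.

## Known limitations

- Layer-tied mode collapses the 128 feature channels to one effective
  scalar (all filters of the last layer share a kernel); it is the right
  desk-scale default but wastes the head's capacity. Untied mode lifts
  this at ~30× the stage-1 cost.
- The TSO is a documented transit-search-*style* scheme, not a
  reproduction of any published variant's exact update equations.
- The segmentation stage is classical (clustering + morphology), not
  learned; it detects bright compact lesions and will miss
  non-enhancing, infiltrative, or strongly heterogeneous ones.
- Real-data mode assumes co-registered, skull-on or skull-stripped
  BraTS-style inputs; there is no registration or bias-field correction.
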