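# Methods

`barilearn` implements a supervised manifold-learning pipeline for
predicting the success of Roux-en-Y gastric bypass (RYGB), measured as
percent total weight loss one year after surgery,

    %TWL = 100 · (basal − one-year) / basal,

from a panel of 60 preoperative clinical, anthropometric and biochemical
variables. Basal weight is taken before the one-month very-low-calorie
diet that precedes surgery. A procedure counts as a *success* when
%TWL ≥ 30 (boundary inclusive); *failure* (%TWL < 30) is the positive
class in all classification metrics, because the clinical use case is
flagging patients at risk of an insufficient response.

## Model

The pipeline has five stages.

**1. Normalization.** Every variable is z-scored, y = (x − x̄)/σ, with the
population SD convention (denominator n). The convention is a choice —
nothing downstream depends on it as long as it is used consistently, which
the `NormStats` object enforces by carrying the statistics with the data.
By default statistics are fitted on the training split only and applied to
held-out patients; a `whole-sample` mode normalizes over the full cohort
instead. Whole-sample normalization leaks validation information into the
training representation, which is why it is not the default, but it is
retained as an explicit mode for comparability with analyses that
normalize "over the study sample". Zero-variance and missing variables are
hard errors: the pipeline assumes such variables were dropped upstream and
never imputes.

**2. Exponential weighting.** Each normalized variable is scaled by a
power of ten, z_v = 10^{α_v}·y_v, with α_v ∈ [−4, +4], so variable
influence spans 0.0001–10,000×. The α vector is the model's interpretable
parameterization: a variable's evolved exponent is a direct measure of its
relevance to the outcome. One variable — by convention the first binary
sex/gender indicator — is pinned at α = 0 as the scale reference, leaving
V − 1 = 59 free exponents on the default panel.

**3. Locally linear embedding (LLE).** The weighted training matrix is
embedded into d = 3 coordinates by classic LLE: k = 7 Euclidean nearest
neighbours per patient; barycentric reconstruction weights per patient
solving the local Gram system G w = 1 (then normalized to sum to one) with
ridge G += reg·trace(G)·I, reg = 1e-3; embedding coordinates from the
bottom non-constant eigenvectors of M = (I − W)ᵀ(I − W), solved densely
(cohorts are O(100) rows; a dense symmetric solver is faster and more
robust than sparse iteration at this size). Coordinates are unit-norm
eigenvectors, centered by construction. k = 7 matches the neighbour count
of the out-of-sample stage, keeping the training and projection geometry
coherent; it is configurable.

Eigenvector signs and the eigen-order of the coordinates are
solver-arbitrary, so neither is given meaning: `orient_to_outcome` selects
the coordinate with the highest squared Pearson correlation with training
%TWL, calls it w2, and fixes its sign so that low w2 means low weight
loss. All downstream results are invariant to the solver's sign choices.

**4. Evolutionary optimization of α.** The objective of a candidate α is
the largest squared Pearson correlation R² between any of the three
embedding coordinates and training %TWL — i.e. the search tries to force
one latent direction to align with the outcome. The optimizer is a
real-coded genetic algorithm: uniform initialization in [−4, 4] (reference
gene pinned at 0), tournament selection of size 3, BLX-0.5 blend crossover
with probability 0.7, per-gene Gaussian mutation (SD 0.4, probability 1/V)
with clipping, elitism of one. These operator choices are standard
real-coded GA defaults; all are configurable. Candidates that collapse the
embedding (zero-variance coordinate, singular systems) score 0 rather than
raising, so the search is robust across the whole α box.

The reference configuration is 1200 individuals × 10,000 generations × 3
independent repetitions (36 million evaluations); `EAConfig.reference_scale()`
represents it. The package's working default is `EAConfig.desk_scale()` —
60 × 200 × 3 — which completes in well under a minute per cohort and is
the budget used throughout the test suite. The optimization is explicitly
budget-bounded: no convergence criterion is imposed (at these budgets the
search does not converge, and independent repetitions differ), and the
contract is a full best-per-generation trace plus elitism-guaranteed
monotonicity. The best run (highest R², ties to the lowest run index)
supplies the final exponents; exponents are also compared *across* runs to
flag consensus-high (α ≥ 2.4 in every run) and consensus-low (α ≤ −2.4,
a symmetric convention) variables.

**5. Out-of-sample projection and thresholding.** A held-out patient is
placed in the latent space by the barycentric scheme LLE itself uses: find
the m = 7 nearest training patients in the *weighted* variable space,
solve influence weights β (sum-to-one constrained least squares, same
ridge as stage 3), and set W_v = Σ β_i·W_ti. The sum-to-one constraint
makes the projection affine-equivariant and exact-match-faithful; an
unconstrained mode and an unweighted-distance mode exist for sensitivity
analysis. Classification thresholds the projected w2: predict failure iff
w2 < w2u (the boundary goes to success). Sweeping w2u over all midpoints
between adjacent distinct w2 values (plus ±∞ sentinels) realizes every
possible threshold; AUC is the trapezoidal area, computed in integer
pair-count arithmetic so it equals the Mann–Whitney concordance
probability exactly (ties counted half). The reported operating point
maximizes Youden's J = sensitivity − FPR, ties resolved toward the lower
threshold; a closest-to-corner criterion would be a reasonable
alternative, J is simply the standard reading of an "optimal" ROC point.

**Pruning.** `prune_and_reembed` drops variables with α below a cutoff
(default 2.4) and re-evaluates. `reuse` mode keeps the surviving exponents
fixed and re-runs embedding → projection → ROC; `refit` re-runs the GA on
the reduced panel. If the reference variable is pruned, the surviving
exponents are re-based so the first survivor becomes the new zero — a
uniform shift multiplies every column by the same constant, which changes
no neighbourhood, barycentric weight or embedding.

## Synthetic cohorts

Real patient data for this problem is not publicly available, so the
package ships a first-class generator (`barilearn.synthetic`) that
emulates the structure the pipeline assumes, with known ground truth:

- 118 patients × the 60-variable panel by default; 15 binary variables
  (comorbidities, medications, sex) as Bernoulli draws, 45 continuous
  variables as Normals. Marginals for the anthropometrics, blood pressure,
  glycemia, lipids and major comorbidity prevalences are calibrated to the
  published baseline table of the cohort this pipeline was designed
  around; other analytes use typical reference values for severely obese
  adults.
- %TWL = intercept + Σ effect_j·standardized(x_j) + Normal(0, noise_sd).
  Default: nine informative variables (sleep apnea, osteoarthritis,
  insulin treatment, preoperative weight, HOMA-IR, Apo A, uric acid,
  complement C3, vitamin B12 — the consensus-relevant panel of the source
  analysis), effect 3.0 %TWL points per SD each, noise_sd 8 (the scale
  reported for comparable one-year %TWL cohorts). The intercept is solved
  so the expected success prevalence is 0.61; because binary predictors
  make the signal non-Gaussian, it is obtained as a Monte Carlo quantile
  (200,000 draws, fixed internal seed), deterministic given the config.
- Basal and one-year weights are back-solved from the drawn %TWL (basal is
  the cohort's own pre-VLCD weight variable), so `compute_twl` reproduces
  the drawn outcome to float precision. %TWL is capped at 99 to keep
  one-year weights positive; weights are floored at 40 kg.
- `null_generate` produces the matched null world: identical marginals,
  no informative variables — the reference for chance-level calibration
  of the optimizer and ROC stages.
- Variables are independent by default (the real cohort's covariance is
  unpublished; independence is the honest default). Options: equicorrelated
  Gaussian-copula blocks for comorbidity co-occurrence, and a two-stratum
  mode drawing the sex-dimorphic anthropometrics conditional on sex.

What the generator does *not* emulate: realistic inter-variable
correlation structure (unless configured), non-linear or interaction
effects on the outcome, missingness, measurement error, site effects, or
the VLCD phase as a process. Tests passing on these cohorts therefore
demonstrate that the machinery is correct and can recover planted linear
signal at realistic n/V and noise — not that the clinical effect sizes or
discrimination levels reported on any real cohort are reproducible.

## Numerical choices and edge cases

- Gram/ridge: reg·trace(G)·I with reg = 1e-3 everywhere a local system is
  solved; when trace(G) = 0 (all neighbours coincident) an absolute reg·I
  floor is used. reg = 0 is allowed and raises on singular systems.
- kNN ties break toward the lower row index (stable argsort); a point is
  never its own neighbour. Inside the GA objective the k smallest are
  selected without a full sort — neighbour *order* does not enter the
  embedding cost matrix.
- The bottom eigenvector of M (the constant, eigenvalue 0 by the
  sum-to-one rows) is discarded positionally. If the neighbour graph is
  disconnected, M has additional ~0 eigenvalues whose eigenvectors are
  component indicators; the embedding then separates components rather
  than tracing a manifold. This is intrinsic to LLE; with k = 7 on
  cohort-sized data it does not arise, but tiny-k constructions can
  trigger it.
- Split sizing is round-half-up (118 × 0.7 → 83); the split is plain
  uniform sampling by default, with an optional outcome-stratified mode.
- Train/validation AUC needs both classes present in the validation set;
  a single-class validation set raises.
- All randomness flows through explicit integer seeds (split seed, GA base
  seed + run index, generator seed); every pipeline stage is otherwise
  deterministic, and a full run re-executed with the same config writes
  byte-identical artifacts.

## Problem sizes used in the test suite

The acceptance-level property tests run the full pipeline at the study's
own scale (n = 118, V = 60, 70/30 split) with the desk-scale GA budget:
parameter recovery pools ten seeded cohorts (60 × 200 × 3 each), null
calibration ten seeded null cohorts with a single GA run each (under the
null, validation discrimination is chance-level regardless of how hard the
training objective is optimized, so repetitions add nothing), and pruning
robustness uses single-run fits. Oracle-equivalence tests (dense
eigendecomposition, constrained least squares, pair-counting AUC) run on
n ≤ 60 instances where the independent oracles are cheap and exact.

## Known limitations

- The GA objective is a training-set correlation; at n = 83 training
  patients a three-coordinate nonlinear embedding can reach R² ≈ 0.4 even
  on null data. Training R² is therefore a search objective, not a
  validity measure — validity rests entirely on the held-out ROC.
- The discovered w2 is identified only up to the embedding's nonlinear
  reparameterizations; its numeric scale (hence the w2u threshold) is not
  comparable across fits.
- LLE assumes locally linear neighbourhoods; strongly clustered or
  disconnected weighted geometries degrade it (see above).
- The pipeline predicts one outcome at one horizon; no survival/longitudinal
  structure, no calibration of predicted probabilities, and no alternative
  discrimination indices are provided.
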