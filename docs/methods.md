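# Methods

This note documents the models, numerical choices and known limitations
of `connpredict`, in the spirit of a package methods appendix. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Feature model

A subject's functional connectome is the R×R Pearson correlation matrix
of regional mean time series (R = 246 by default, mirroring a standard
whole-brain parcellation of 210 cortical + 36 subcortical regions).
Matrices must be symmetric (tolerance 1e-12), have exact unit diagonal
and entries in [−1, 1]; a zero-variance regional signal is treated as a
data error, not a zero correlation.

Nodal connectivity strength is the **signed** sum of a region's
correlations to all other regions (R−1 terms; the diagonal is excluded by
construction, never zeroed-and-summed). No Fisher z-transform, absolute
value or threshold is applied by default: with global-signal regression
upstream, negative correlations are common and informative. `fisher_z`
and `absolute` switches exist for sensitivity analyses only.

Edge features over a region subset of size K are the upper-triangular
correlations among those regions in atlas order, length K(K−1)/2
(1,225 for K = 50).

## Relevance vector regression

The engine is written from scratch (it is the package's core) and
implements the classic sparse Bayesian regression with a linear kernel:

    f(x) = Σ_s β_s (x·x_s) + β_0,   β_i ~ N(0, α_i⁻¹),  y = f(x) + ε,
    ε ~ N(0, σ²)

with type-II maximum-likelihood (evidence) optimisation of the
hyperparameters by the full fixed-point updates

    γ_i = 1 − α_i Σ_ii,   α_i ← γ_i / μ_i²,
    σ² ← ‖y − Φμ‖² / (n − Σ_i γ_i),

where μ, Σ are the weight posterior mean/covariance given (α, σ²) and
Φ = [1 | K] is the kernel design with an explicit bias column. Numerical
choices, all logged in serialized models:

- prune threshold α > 1e9 (the bias column's α is capped there instead of
  pruned, so the intercept always survives);
- convergence when max |Δ log α| < 1e-6, cap of 1,000 iterations, plus
  one final posterior evaluation so reported weights are consistent with
  the final hyperparameters;
- deterministic initialisation α = 1/n, σ² = 0.1·var(y) — fits are
  bit-reproducible; σ² floored at 1e-12 for interpolable targets;
- a weight whose squared posterior mean underflows (< 1e-300) is treated
  as pruned rather than dividing by zero;
- if the posterior precision loses positive definiteness to rounding, an
  escalating diagonal jitter (starting at 1e-10) is applied and a warning
  emitted.

The log marginal likelihood is evaluated every iteration via the
determinant identity |C| = σ²ⁿ|H|/Πα and is checked (in tests) to be
non-decreasing to 1e-8 slack. With α updates frozen at a shared value the
posterior mean reduces exactly to kernel ridge regression, which the
tests exploit as a closed-form oracle; a dense grid search over shared
(log α, log σ²) provides an independent lower bound that the fitted
evidence must attain.

Exact scale equivariance (y → cy) holds for the update *dynamics* when
the initial α is scaled by 1/c²; the default initialisation is not
scale-covariant, so default fits on rescaled targets can land in nearby
(not bit-identical) evidence optima. The hot loop is jitted with numba
(hand-rolled Cholesky/triangular kernels, since numba cannot catch LAPACK
failures); a pure-numpy fallback runs identically if numba is absent.

## Cross-validation protocol

Per fold, each feature is min–max scaled on the training rows only and
the same affine map is applied to the test rows (values outside [0, 1]
are retained; a zero-range feature maps to 0 everywhere). The model never
sees held-out rows — the suite enforces this by poisoning test rows with
NaN and asserting bitwise-identical fits.

Schemes: leave-one-out (deterministic) and repeated k-fold (default
k = 10, 20 repeats). K-fold partitions come from scikit-learn's shuffled
`KFold` (the first n mod k folds take the extra subject) with the RNG
derived from `SeedSequence([seed, repeat])`; reported metrics are the
mean of per-repeat metrics, not pooled-prediction metrics.

Accuracy: Pearson r; partial r computed by residualising observed and
predicted scores on [1, covariates] (sex coded 0/1; multi-level
categoricals one-hot with first level dropped); MAE on the raw score
scale (the covariate adjustment never touches MAE).

## Permutation significance

Each permutation shuffles the score vector once, globally, without
replacement (RNG `[seed, b]`) and re-runs the full CV — all folds, all
repeats, model refits included; fold layouts and scaling parameters
depend only on the features and are shared with the observed run, which
is an exact optimisation, not an approximation. Covariates are never
permuted; partial r is recomputed against the unpermuted covariates each
time. P-values are literal proportions with ties counted as exceeding
(conservative); `p = 0` is therefore possible, and a smoothed
`(b+1)/(n_perm+1)` variant is available behind a flag because the
literal rule understates uncertainty at the boundary. A failing
permutation run is excluded and counted; more than 1% failures aborts.

## Interpretation stages

The full-sample contribution model min–max scales over all subjects
(there is no held-out set at that stage), fits once, and back-projects
`w = Σ_s β_s x_s`; features are ranked by |w| with exact ties broken by
atlas index (deterministic). The edge-level second stage reuses the
full-sample top-k regions; because that selection saw all subjects, its
CV metrics are labelled interpretive, and `nested_edge_loocv` provides a
fully nested alternative (top-k re-selected inside every training fold).
Network aggregation sums |w| over edges per unordered system pair
(signed sums are emitted as a secondary output); the matrix total equals
Σ|w| exactly, which the suite asserts.

Region-wise validation screens (nodal strength vs age, daytime
sleepiness or head motion, controlling the remaining covariates) use
partial correlation with the t-transform p-value (df = n−2−q) and
Benjamini–Hochberg FDR (statsmodels) at q = 0.05 by default.

## Synthetic cohorts

The generator emulates the study conditions the pipeline targets:
cohorts of ~29–44 subjects, 246 regions, a 0–21 integer score with
mean 18.4 and SD 2.3 (the chronic-cohort values; the acute-cohort
16.6 ± 3.2 is a config away), and covariates drawn independently of the
score. Scores are drawn from the continuous normal, rounded to integers
and clipped to [0, 21]; the clipping noticeably truncates the upper tail
at these parameters, and the test suite checks the realised moments
against numerically integrated rounded-truncated-normal moments rather
than the raw normal parameters.

The base connectome is block-structured over the seven cognitive systems
(within-system r = 0.3, between 0.05). Every edge gets independent
N(0, noise_sd²) noise; edges joining two *planted* regions are shifted by
`effect_size · z(y_i)` with z the cohort z-score of the subject's score.
Planting only the planted–planted block is deliberate: it keeps the
nodal and edge stages' targets distinct (planted regions accumulate the
shift over K−1 planted neighbours, unplanted regions carry pure noise).
Shifting *all* edges incident to planted regions instead would make every
region's strength collinear with the score, and after per-fold min–max
scaling planted regions would be unrecoverable by weight ranking.

Perturbed matrices are projected back to valid correlation matrices. The
default repair is the one-shot eigenvalue-clipping projection
(statsmodels `corr_clipped`: clip negative eigenvalues, renormalise the
diagonal) because a cohort can require thousands of repairs; a full
Higham alternating-projection nearest-correlation search (tolerance
1e-8, up to 200 iterations — alternating projection converges linearly
and routinely needs >100 iterations on these matrices) is available as
`repair="nearest"` and is cross-checked against statsmodels
`corr_nearest`.

`effect_size = 0.5` and `noise_sd = 0.05` are the defaults: there is no
empirical anchor for the true connectome→score coupling, so they are
chosen once to make planted signal clearly recoverable (out-of-sample
r ≈ 0.85–0.95 at n = 44–100) while leaving a genuine estimation problem;
`effect_size = 0` gives exact null cohorts used to calibrate the
permutation test. Time-series simulation (multivariate normal with the
subject's connectome as population correlation) exists so the
correlation-estimation step can be tested end-to-end; empirical
correlations obey the Fisher-z variance 1/(T−3), which the suite checks.

What the generator does **not** emulate: spatial autocorrelation and
distance-dependence of real connectomes, scanner/site effects, heavy
tails and motion artefacts, non-linear connectome–behaviour coupling.
Passing tests therefore demonstrate correctness and calibration of the
*pipeline*, not expected accuracy on real patient data — with real
cohorts of n ≈ 30–44, out-of-sample correlations are typically far
lower than on these planted-signal cohorts.

## Problem sizes used by the checks

The acceptance suite uses the study conditions directly where feasible:
planted-signal recovery runs 20 cohorts of n = 100 subjects × 246
regions; permutation calibration runs 50 null cohorts (n = 30) at 200
permutations each under single-repeat 10-fold CV (calibration is
scheme-agnostic, and 10 refits per permutation keep the check tractable);
`scripts/acceptance.py` uses n = 44 subjects, 246 regions and 500
permutations per stage. These sizes are the package's own choices for a
thorough-but-tractable default; all are parameters, not constants.

## Known limitations

- The evidence surface is multimodal; the fixed-point scheme finds a
  local optimum. This matches standard practice but means fits are only
  guaranteed reproducible, not globally optimal.
- The literal-proportion p-value can be exactly 0; report the smoothed
  variant when publishing boundary cases.
- The second-stage (edge-level) CV metrics are optimistic by
  construction when the default (non-nested) region selection is used;
  use `nested_edge_loocv` for honest edge-stage accuracy.
- `corr_clipped` repair is near- but not exactly nearest-correlation;
  for very large perturbations the planted-signal geometry is distorted
  (the clipping also saturates extreme planted edges at |r| = 1).
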