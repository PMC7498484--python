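# Methods

## Design splitting

Covariates enter as an L×M table (subjects × covariates); categorical
variables are expected pre-encoded as numeric/dummy columns. Optional
preprocessing scales each column to unit norm (`normalize`), residualizes
later columns on earlier ones by sequential Gram–Schmidt
(`orthogonalize` — order follows the file, so confounders should come
first), or both (`orthonormalize`). The `demean` flag first residualizes
every column on the constant; this aligns preprocessing with the
intercept that is always part of the corrector model, and is what makes
two-stage fitting exactly reproduce a joint fit (see below).

A contrast matrix C (M×P, full column rank) defines the predictor
subspace X_P = XC; the null-contrast C₀ = I − CC# (Moore–Penrose
pseudoinverse, singular values below 1e-8 of the largest treated as
zero) defines the corrector subspace X_C = XC₀. Numerically zero
columns of X_C are dropped and their indices recorded. The two
subspaces are orthogonal only when the columns of X are.

## Two-stage fitting

The corrector model is fitted to the observations and the predictor
model to its residuals. An intercept is always part of the corrector
stage (an intercept-only stage when no correctors exist), so the
predictor always sees mean-centered residuals; the predictor stage adds
no second intercept beyond what its family needs. Any family can serve
at either stage. When the covariates are orthogonalized with
`demean=True`, the concatenated two-stage GLM predictions equal a joint
least-squares fit on [1, X_C, X_P] to machine precision; without
orthogonalization the two-stage result is order-dependent by design
(confound removal first), which is the intended semantics.

All fitters process observations strictly one at a time, which makes
fitting in chunks of any size bit-identical to fitting everything at
once — chunking is purely a memory knob.

### GLM

Each design column x_j is expanded to powers x_j, …, x_j^{d_j}; the
coefficients are ordinary least squares via a precomputed pseudoinverse
of the expanded design. df = Σ d_j (the intercept is accounted
separately, as +1 in the corrector df). A rank-deficient expanded
design raises rather than silently regularizing.

### GAM

The additive model y = α + Σ f_j(x_j) is estimated by backfitting:
cyclically refit smoother j to the partial residual
y − α − Σ_{k≠j} f_k, center the refitted component to mean zero
(the additive model's identifiability gauge; α = ȳ absorbs the means),
and stop when the largest component change drops below `tol`
(default 1e-6) or after `max_iter` (default 500) sweeps —
non-convergence is a recorded warning, not an error. Each smoother
fits with an own intercept column that the centering removes again;
this makes every smoother a projection onto span(1, basis), and with
linear or polynomial smoothers the converged GAM equals the
corresponding GLM. Spline bases are built with patsy: B-splines
(`bs`, knots at covariate quantiles) and natural cubic splines (`cr`,
linear beyond the boundary knots); a spline of df k needs at least
k+1 distinct covariate values. df = Σ smoother df (1 for linear, the
degree for polynomial, the user-set df for splines).

### ε-SVR

Per-observation support vector regression through scikit-learn, kernels
polynomial and RBF (k = exp(−γ‖x−x′‖²)). The fitted machine is stored
as the kernel expansion f(x) = Σ_l k(x^l, x)β_l + b over the training
points (β the dual coefficients). Effective df is the count of marginal
support vectors — dual coefficients strictly inside (0, C) — with a
kernel-trace estimate `tr[K(K + I/C)⁻¹]` available behind
`df_mode="kernel_trace"`; both are floored at 1. A design with no
variation yields the constant mean model with df 1.

Hyperparameters (C, γ, ε) can be chosen by grid search: H combinations
sampled linearly, logarithmically or at random from per-axis ranges (or
given explicitly); each combination is fitted on re-drawn subsets G of
the eligible observations (variance ≥ σ_min) and scored by the
inverse-variance-weighted sum of a per-observation metric (residual
SSE, F-test p-value, or Mallows's C_p against the most flexible model
in the search space, whose residual variance supplies the needed noise
estimate). Ties break toward smaller C, then smaller γ; subset draws
are seeded.

## Inference metrics

MSE is stored as the residual sum of squares ‖y − f(X)‖² (the
`mean=True` accessor divides by L); AIC uses the per-sample mean m̄ =
SS/L, AIC = 2k + L(log(2π·m̄) + 1), with k the total fitted parameter
count including the intercept. R² is taken about the observation mean
and is NaN for zero-variance observations. The nested-model F-test
compares the corrector-only fit (SS_res) against correctors+predictors
(SS_full):

    f = ((SS_res − SS_full)/SS_full) · ((L − df_full)/(df_full − df_r))

with p the upper tail of F(df_full − df_r, L − df_full); df_full may be
per-observation (SVR). Negative f from numerical round-off is clamped
to 0. Perfect full fits yield the sentinel p = 0 with a warning.

PRSS penalizes the *shape* of the fitted predictor curve rather than
its df: c_abruptness is the trapezoidal integral of the squared second
derivative of the curve over its evaluation grid (second derivatives by
`np.gradient` twice with second-order edges, exact for quadratics), so
any fitter that produces a straight curve pays nothing regardless of
family. γ defaults to 1. An absolute-value integrand is available as a
variant. VNPRSS divides PRSS by the curve's variance about the mean of
the corrected observations; a constant curve gives the NaN sentinel.

Curves are evaluated on a uniform grid of T = 100 points over the
training predictor range (the first predictor column is swept;
additional predictor columns are held at their training means).
Extrapolation beyond the range is allowed but warned about.

Thresholded F-test maps can be cleaned with uncorrected p-thresholding
plus 6-connectivity cluster-extent filtering; Bonferroni is available
by dividing the threshold, and no random-field or permutation
inference is attempted.

## Post-hoc analysis

Comparison maps: diff/ABSdiff/SE for two maps, RGB for three
(per-channel min–max rescaled over the mask), best-map for two or more
(argmax for F/R², argmin for MSE/AIC/PRSS; mixed metrics require an
explicit polarity; ties go to the lowest model index).

Curve clustering uses the derivative-weighted distance
SD(x,y) = Σₙ wₙ dₙ with dₙ the Euclidean distance between the n-th
discrete derivatives (plain n-fold differencing of the curve sequence;
a `step` parameter rescales to physical units if wanted) and defaults
N_D = 3, w = [0.2, 0.8, 0.2]. Each dₙ is divided by √(T−n) by default
so the weights compare like with like across the shrinking support.
Curves are z-scored over the grid before clustering (shapes, not
amplitudes; switchable off). Agglomeration is bottom-up average
linkage, implemented directly via Lance–Williams updates so that merge
ties deterministically break toward the smallest pair indices; the
merge history is returned, and scipy's hierarchical clustering serves
as an independent cross-check in the test suite. Cluster diagnostics:
mean silhouette under SD (singletons contribute 0), mean distance to
the own centroid (within) and mean pairwise centroid distance
(between). Which curves enter clustering is controlled by a p-value
threshold on a chosen map plus an optional extent filter.

## Synthetic phantoms

The generator emulates a cross-sectional morphometry study: L = 80
subjects by default, 16³ volumes, a disease-staging predictor uniform
on [0, 2], age uniform on [45, 75] and Bernoulli(1/2) sex. Disjoint
regions (three 3³ cubes by default) carry one response family each —
null, linear (a·x, a = 0.5), quadratic (a·x², a = 0.3) or sigmoid
(a/(1+e^{−5(x−1)}), a = 1.0, steepest mid-continuum) — on top of
corrector effects (age slope −0.02/yr about the mean age, quadratic
age 5e-4, sex offset 0.1) and i.i.d. Gaussian noise (σ = 0.3,
a moderate signal-to-noise ratio for the region effects). Everything
derives from one seed and is bit-reproducible. The default sizes keep
an F-test on the quadratic region essentially always significant at
p < 0.001 while single tests stay honestly calibrated under the null.

What the phantom does **not** emulate: spatial autocorrelation, scanner
and site effects, realistic anatomy, or covariate collinearity beyond
what the user injects. Passing tests therefore demonstrate the
correctness of the estimators and pipeline plumbing, not robustness to
real-data artifacts.

Curve-set fixtures perturb family curves with small i.i.d. grid noise;
because the clustering distance differentiates the sequence, recovery
claims hold at low noise (σ ≈ 0.01 on unit-scale curves) — real fitted
curves are smooth by construction and do not have this failure mode.

## Pipeline and formats

Stages (generate-phantom, fit, infer, compare, cluster, show-curves,
show-data-distribution) share a YAML config; each writes a manifest
(parameters, seed, version) and re-checks its prerequisites' manifests,
and the effective config is echoed to the output directory. Subjects
align to covariate rows by sorted file order; geometry mismatches name
the offending file. Observations with variance ≤ σ_min (default:
exactly constant) are masked out; masked locations are written as 0 in
output maps, which keep the input format and affine. The fitted model
is persisted as an `.npz` of parameter arrays plus a JSON sidecar of
specs — an internal layout sufficient to re-derive predictions and
curves without refitting. Volume coordinates for `show-curves` are
world-space mm mapped through the inverse affine to the nearest voxel;
surfaces take a vertex index.

## Numerical choices

- Pseudoinverse tolerance 1e-8 relative to the largest singular value.
- Backfitting: tol 1e-6 on the max absolute component change, 500
  sweeps maximum.
- Marginal support vectors: |β| within (1e-10·C, C·(1−1e-10)).
- Zero-variance voxels, zero SS_y, and constant curves produce NaN
  sentinels that stay confined to their own observation.
- Map values are written as float32 (integer-valued maps round-trip
  exactly within float32 range).

## Known limitations

- SVR effective df follows the marginal-support-vector rule; other df
  estimators for kernel machines exist and would shift F-test dfs.
- Backfitting convergence slows as covariates become collinear; the
  non-convergence warning should be heeded.
- The grid search scores by training error on observation subsets
  (optionally penalized via C_p); it does not cross-validate.
- No FDR/RFT/permutation correction; cluster-extent filtering with an
  uncorrected threshold is the only spatial cleanup.
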