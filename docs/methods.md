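# Methods

## Model and procedure

`mirlasso` treats the joint vector of miRNA and mRNA expression values as a
multivariate Gaussian and identifies candidate interactions through the
support of the precision matrix θ = Σ⁻¹: θ_ab ≠ 0 means a and b are
conditionally dependent given all other profiled features, which is a far
stronger statement than marginal correlation and is what makes hub analysis
meaningful. θ is estimated by maximizing the penalized log-likelihood

    log det θ − tr(Sθ) − ρ‖θ‖₁,

where S is the empirical covariance of the integrated matrix Z and
‖θ‖₁ = Σ_ij |θ_ij| is the entrywise L1 norm. The penalty is applied
uniformly, diagonal included, which pins the dual covariance diagonal at
W_ii = S_ii + ρ; `penalize_diagonal=False` reproduces the convention of
solvers that leave the diagonal free (scikit-learn's among them) and is
used for cross-checks.

The full procedure is sequential: a two-group differential-expression
screen first reduces each feature class, only the surviving features enter
Z, and the reported network is the bipartite (miRNA–mRNA) part of the
estimated support.

## Solver

The estimator is the block coordinate descent of the graphical-lasso
family: cycle over columns of W, solve each column's lasso subproblem

    min_β ½ β'W₁₁β − s₁₂'β + ρ‖β‖₁

by cyclic coordinate descent with soft-thresholding, update the column,
and at convergence recover θ blockwise from the lasso coefficients
(θ_jj = 1/(W_jj − w₁₂'β), θ_·j = −β θ_jj). Cycling order is input order
with no randomization, so results are bit-reproducible for fixed inputs
and tolerances. The numerical kernels are JIT-compiled with numba.

Numerical choices:

- **Covariance divisor 1/n** (maximum-likelihood form), matching the
  likelihood; 1/(n−1) would silently rescale the effective penalty.
- **Outer tolerance** 1e-4, *relative*: convergence when the mean absolute
  per-sweep change of W off-diagonals falls below tol × mean|S_offdiag|
  (tol itself for diagonal S). Inner lasso tolerance 1e-6 on coefficient
  changes; 100 outer sweeps maximum. All exposed through `fit()`.
- **Certificates.** Every fit reports the KKT bound violation
  max(|W−S|_∞ − ρ, 0) over off-diagonals, the active-set residual
  max|W_ab − S_ab − ρ·sign(θ_ab)| over edges, and the duality gap
  tr(Sθ) + ρ‖θ‖₁ − m. Non-convergence returns a flagged result; network
  construction then requires `force=True`.
- **Edge definition**: |θ_ab| > 1e-8 after convergence. A hard numeric
  zero would be solver-dependent.
- **Degenerate inputs.** Constant features are removed (and reported)
  before covariance estimation, since S would otherwise have a zero
  diagonal entry. ρ = 0 requires a nonsingular S. A non-positive pivot
  during θ recovery raises rather than returning an indefinite estimate.
- **Warm starts.** `regularization_path` sorts penalties decreasing and
  warm-starts each fit from the previous solution; path edge counts are
  monotone at the endpoints but not guaranteed monotone pointwise.

An independent validation solver (`glasso_reference`) optimizes the same
objective by FISTA with backtracking and momentum restarts, evaluated
through a Cholesky factorization (which doubles as the positive-definite
test — a determinant-sign test would miss matrices with an even number of
negative eigenvalues). It shares no code with the production solver and is
used in tests to certify agreement to below 1e-4.

## Differential-expression screen

Grouping rules: one-year survival (≤ 365 days is high-risk, recorded
survival used as-is — censoring is deliberately not modelled), estrogen
receptor status, and pathological stage (I/II vs III/IV). Samples with an
absent endpoint are excluded and reported.

The test is the pooled-variance (Student's) two-sample t-test, computed on
values as loaded; an optional log2(x+1) pre-transform is off by default.
The screen keeps features with P < 0.05, then requires fold change
strictly above 1.5 or strictly below 0.667 (the printed thresholds are
used verbatim; 0.667 ≠ 1/1.5 by 3·10⁻⁴, a deliberate, documented
asymmetry). Fold change is group A mean over group B mean — group A being
the high-risk / ER-negative / late-stage side — so "up" means up in the
worse-prognosis group; the pass set is unaffected by the convention. An
undefined fold change (zero denominator mean) fails the screen. The
degenerate t-test (both groups constant) returns P = 1 when the means are
equal and P = 0 otherwise, avoiding NaN propagation. No multiple-testing
correction is applied: the screen is a deliberately nonstringent feature
reducer, not an error-rate-controlled discovery procedure.

## Scaling, transforms and the penalty

ρ only has meaning relative to the scale of S. The defaults for network
estimation are log2(count+1) followed by correlation scaling (unit
diagonal), under which useful penalties lie roughly in (0.05, 0.5) for
cohort-sized n; ρ = 2.0 — the default carried by the model for strict
fidelity to covariance-scale analyses — fully shrinks a correlation-scaled
problem to a diagonal θ. On correlation scale the edge set is invariant to
per-feature rescaling of the input (tested).

**Group centring.** The covariance may be formed after centring each
clinical group on its own mean (`center="group"` in the pipeline,
`groups=` in `empirical_covariance`). This matters: the screen guarantees
every feature entering Z differs in mean between the groups, so with
grand-mean centring the group shift acts as a shared rank-one latent
factor that inflates apparent correlations among all DE features (on
planted count data with log2 effect 2.0, typical spurious |correlations|
around 0.4, enough to bury a planted partial correlation of 0.25). Pooled
within-group centring removes exactly this nuisance and recovers planted
hub degrees exactly in the closure tests. The default remains grand-mean
centring, which is the classical empirical covariance of Z.

## Synthetic data generator

`make_precision` builds a planted precision matrix: unit diagonal,
hub-miRNA-to-mRNA entries of magnitude `offdiag_value` (random sign,
targets sampled without replacement), then a ridge δ·I with the smallest
δ ≥ 0 bringing the minimum eigenvalue to 0.1. `sample_expression` draws
latent vectors from N(μ_g, θ⁻¹) on a log2-expression-like scale (baseline
5.0), shifts group A by ±`de_effect_log2` on the planted DE features, and
emits either the latent values (`gaussian`) or negative-binomial read
counts with mean 2^latent and fixed dispersion 0.1 (`nb_counts`; the
dispersion is a structural constant, not a fitted quantity). The clinical
table encodes the two groups consistently under all three grouping rules.
All randomness flows through a single `numpy.random.Generator(PCG64(seed))`,
so fixed seeds reproduce data exactly across platforms.

What the generator emulates: two-group design, planted DE features
(by default exactly the network-connected features, mirroring the
sequential design in which the DE gate feeds the network stage; disjoint
and random plantings are available), a sparse joint dependence structure
with hub miRNAs, and count-like noise. What it does not emulate: library
size variation, batch effects, seed-sequence-based targeting, the
mixed-sign marginal correlations of real miRNA repression, or missing
data. Passing recovery tests therefore demonstrates correctness of the
estimation machinery under the model's own assumptions, not performance
on real tumour cohorts.

## Problem sizes used in tests and the acceptance script

Solver validation uses 50 random problems with m ∈ {3..6} features at
n = 100 against the FISTA reference, and 100 random fits (m ∈ {4..8}) for
KKT certification. DE calibration pools 20 replicates of 500 features at
n = 200 per group. Support recovery uses 20 miRNAs with five planted hubs
of degree 10 over 200 mRNAs, n = 600 Gaussian samples, and a penalty path
{0.3, 0.2, 0.15, 0.1, 0.07, 0.05} on correlation scale, averaged over 10
seeds; best-path bipartite F1 against the planted edge set is essentially
1.0 at these settings. End-to-end runs use negative-binomial counts
(n = 300 per group, planted hub degrees 14/11/8/5, log2 effect 2.0,
ρ = 0.15, group centring) and recover the planted hub ordering exactly.
These sizes are the package's validation conditions; all are generated at
run time by the synthetic module.

## Known limitations

- The Gaussian likelihood is misspecified for raw counts; the log2
  transform plus correlation scaling is a pragmatic, documented default,
  not a count model.
- A single scalar ρ penalizes miRNA–miRNA, miRNA–mRNA and mRNA–mRNA
  partial dependencies equally; no penalty-selection policy (cross-
  validation, stability selection) is provided, only the path utility.
- Survival censoring is ignored by the one-year grouping rule, faithfully
  to the procedure the pipeline reimplements.
- Edge signs are retained internally (θ_ab magnitudes drive edges) but
  the reports treat interactions as unsigned.
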