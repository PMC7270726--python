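# Methods

## Model and estimation

Each endpoint m is modelled marginally: E(Y_ij^(m)) = g⁻¹(x_ij β^(m))
with canonical link/variance pairs (identity/1, log/μ, logit/μ(1−μ)),
working covariance V_i = A_i^{1/2} R_i(α) A_i^{1/2} φ, and subject-wise
score contributions U_i = D_i' V_i⁻¹ S_i (with observation weights,
U_i = D_i' W_i^{1/2} V_i⁻¹ W_i^{1/2} S_i; the fit stores the
weight-absorbed D and S so downstream formulas are weight-free).
Estimation alternates Fisher scoring for β with moment re-estimation of
(α, φ) from Pearson residuals:

- φ̂ = Σ e_ij² / (N − p).  The denominator follows the Liang–Zeger
  convention; because software dialects differ, `scale_divisor="n"` is
  exposed as an alternative.  This choice matches statsmodels' GEE,
  which the tests use as an independent oracle (agreement to 1e−6).
- exchangeable: α̂ = [Σᵢ Σ_{j<k} e_ij e_ik] / [φ̂ (Σᵢ nᵢ(nᵢ−1)/2 − p)],
  clipped to (−1/(n_max−1) + 1e−6, 1 − 1e−6) to keep R positive
  definite; ar1 uses lag-1 products with denominator Σᵢ(nᵢ−1) − p;
  unstructured averages products element-wise.

Convergence is max|Δβ| < 1e−6 within 25 sweeps, started from five
Fisher-scoring steps of the independence GLM.  Rows with missing
response or covariates are dropped per model (valid under MCAR); a
subject absent from one model contributes a structural zero to its
stacked score.

## Stacked covariance and bias adjustment

The joint covariance of the stacked coefficients is the multiple-model
sandwich Σ̂ = Ĥ⁻¹ B̂ Ĥ⁻¹ with B̂ = Σᵢ UᵢUᵢ' over stacked per-subject
scores and block-diagonal Ĥ.  Σ̂ is symmetrized as (Σ̂+Σ̂')/2 after
assembly to remove round-off asymmetry.

The small-sample adjustment replaces each cluster residual S_i by
(I − P̂ᵢᵢ)⁻¹ S_i on both sides of B̂, with cluster leverage
P̂ᵢᵢ = D_i M⁻¹ D_i' V_i⁻¹ and M = Σᵢ D_i' V_i⁻¹ D_i, block-diagonal
over models.  Note the sign convention: the derivative of the stacked
score is Ĥ = −M; the leverage uses the positive matrix M⁻¹ so that the
diagonal blocks reproduce the Mancl–DeRouen adjusted single-model
sandwich exactly (for independent Gaussian observations this is the
classical e_i/(1−h_ii) inflation, which the tests verify in closed
form).  (I − P̂ᵢᵢ)⁻¹ is computed by a dense solve per cluster; cluster
sizes are small, so no Woodbury shortcut is needed.

## Tests, reference distributions, intervals

For H₀: Lβ = r the maximum-type Wald statistic is
max_i |(Lβ̂ − r)_i|/ŜE_i with joint reference correlation
diag(ŜE)⁻¹ LΣ̂L' diag(ŜE)⁻¹; the p-value and critical value are
equicoordinate probabilities/quantiles of the multivariate normal or
multivariate t.  The error degrees of freedom default to
df = min_m (K − p^(m)) over the models actually touched by the tested
rows, so an intersection involving only smaller models gets larger df.
Quadratic-form statistics use (Lβ̂−r)'(LΣ̂L')⁻(Lβ̂−r) with chi-squared
(c), F (W/c ~ F_{c,df}) or scaled-F (Hotelling analogy,
W(df−c+1)/(df·c) ~ F_{c,df−c+1}) references; rank-deficient L uses the
Moore–Penrose inverse and c = rank(L), with rank determined from
singular values at tolerance max(dim)·eps·σ_max.

Score tests evaluate the stacked score at a restricted estimate.  The
hypothesis must be block-diagonal (each row touching one model); each
touched model is refit by the Lagrange-multiplier IRWLS update
β̃ ← β̃ − H⁻¹(U − L'λ), which lands exactly on the constraint at every
iteration, with nuisance parameters re-estimated at β̃ each sweep (the
re-estimation schedule is not prescribed anywhere authoritative; we
mirror the unrestricted alternation).  The statistic is built from
LH̃⁻¹U(β̃) with covariance LH̃⁻¹B̃H̃⁻¹L'.  An optional bias adjustment
of B̃ uses the restricted leverage
P̃ᵢᵢ = D_i (M̃⁻¹ − M̃⁻¹L'(LM̃⁻¹L')⁻¹LM̃⁻¹) D_i' V_i⁻¹ (the projection
removes the constrained directions, so restricted leverage is smaller
than unrestricted).  The single-step score procedure is deliberately
not offered as an FWER-controlling procedure — its reference
distribution is valid only under the global null — score tests are
available as local tests inside the closure instead.

Simultaneous intervals (Lβ̂)_i ± q₁₋α ŜE_i invert the single-step
maximum Wald test, so interval i excludes r_i iff the single-step test
rejects row i.  One-sided alternatives are available for Wald tests
only, evaluated at the least-favourable configuration Lβ = r.

## Equicoordinate probabilities

Rectangle probabilities P(max|Z_i| ≤ q) are computed with scipy's
randomized-QMC Genz integrator for the multivariate t, with a fixed
internal seed so p-values and quantiles are reproducible to about three
decimals.  The multivariate normal case is evaluated as a t with
df = 1e8: this agrees with the exact normal rectangle probability to
~4e−5 while being deterministic and roughly 40× faster than scipy's
normal CDF path.  Quantiles are found by Brent root search bracketed by
the perfect-dependence and Bonferroni quantiles (xtol 1e−4).

Singular correlation matrices (from rank-deficient L) are handled in
two steps: coordinates perfectly (anti-)correlated with an earlier one
are dropped exactly — this covers duplicated contrast rows and makes
them provably inert — and any remaining singular case is integrated by
scrambled Sobol sampling (2¹⁴ points, fixed seed) in the reduced
eigenspace, dropping eigenvalues below 1e−10 of the largest.  scipy's
`allow_singular` path is *not* used: it returns incorrect rectangle
probabilities for degenerate correlations.

## Closed testing

All 2^c − 1 intersections of the c elementary hypotheses are tested at
local level α; the adjusted p-value of H_i is the maximum local p over
intersections containing i.  When rank((L)_S) equals the rank of a
superset's rows, the two intersections define the same region and the
subset's test is substituted by the largest such superset (rank-based
reduction).  The substituted test is a valid level-α test of the
identical hypothesis, so FWER control is untouched.  For quadratic-form
local tests the reduction is exactly neutral: with rows C·L_S the
statistic v'C'(CMC')⁺Cv equals v'M⁻¹v for full-column-rank C, so
linearly dependent rows change nothing.  For maximum-type local tests
the superset's p-value differs numerically from the subset's, but since
it already enters every maximum over supersets, the substitution can
only lower adjusted p-values — the power gain that motivates the
reduction.  Both facts are asserted in the tests.  c is capped at 16
(configurable) because the closure grows as 2^c.  Bonferroni local
tests reproduce Bonferroni–Holm exactly, which the tests assert.

## Synthetic data generator

The generator emulates a two-arm study (K/2 subjects per arm, first
half control) with M endpoints in equal thirds continuous, count and
binary, subject-level cluster sizes uniform on {2,3,4} shared across
endpoints, and endpoint-specific covariates that are jointly normal
with pairwise correlation 0.4.  Dependence comes from a latent Gaussian
vector with correlation 0.75 between repeats of one endpoint and a
single constant rho_between ∈ {0, 0.25, 0.5, 0.75} between *all*
cross-endpoint pairs (same- and different-occasion alike — the only
reading consistent with a single stated between-endpoint correlation).
Margins are quantile transforms: normal(μ,1); negative binomial with
size 1 and success probability 1/(1+μ), hence variance μ+μ²; Bernoulli.
Intercepts are (0, 0, −0.75) and the covariate effect 0.25 per endpoint
type; group effects of (0.75, 0.95, 1.5) at K=40 and (0.45, 0.6, 0.9)
at K=100 put the expected standardized marginal statistic near 2.5
(about 70% power for a single unadjusted test).  For other K the K=40
effects are scaled by √(40/K), which preserves that calibration.

What the generator does *not* emulate: missingness mechanisms, unequal
covariate distributions per arm, time trends within subjects, or
endpoint-specific cluster sizes.  A green Monte-Carlo test therefore
establishes calibration under exactly this copula world, not under
arbitrary real-data dependence.

Count endpoints are deliberately analysed with Poisson-family GEE
models: the robust sandwich absorbs the negative-binomial
overdispersion, exercising the robustness the methodology relies on.
The Monte-Carlo harness draws one generator per replicate from
SeedSequence(seed, spawn_key=(rep,)), so results are independent of how
replicates are batched; replicates with failed fits are excluded and
counted, and more than 1% failures aborts the run.  Default replicate
counts in the tests (600–2000) are scaled down from much larger
published-style runs to fit a CI budget; binomial Monte-Carlo envelopes
in the assertions are widened accordingly.

## Numerical and design choices

- Fisher scoring divergence (‖β‖ > 1e8 or non-finite) raises; reaching
  max_iter returns `converged=False` with a warning, and stacking
  refuses unconverged fits.
- An exact fit (all residuals zero) is a degenerate-data error, not a
  silent φ̂ = 0.
- `fixed` working correlation uses the leading n×n principal submatrix
  of the supplied matrix and requires positive definiteness.
- Contrast consistency (rank([L|r]) = rank(L)) is validated at
  construction; infeasible per-model restrictions are rejected before
  iteration.
- The CLI is a thin layer; every number it prints is computed by the
  library functions above.

## Known limitations

- Only the three canonical family/link pairs; no ordinal or
  multinomial endpoints.
- Weights are user-supplied observation-scale factors; no estimation of
  inverse-probability-of-missingness weights (MAR is out of scope).
- No joint (cross-endpoint weighted) estimation of coefficients.
- No score-based confidence sets, no Satterthwaite or effective-sample-
  size degrees of freedom, no weighted closed testing.
- Equicoordinate quantities are QMC-based and reproducible but carry
  ~1e−4 integration error; tests assert at tolerances above that.
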