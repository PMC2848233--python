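# Methods

This note records the statistical machinery implemented in abckit, the
defaults that matter, and the design choices made where the literature
leaves the constants open.

## The inference problem

Given a prior π(θ), a stochastic simulator θ ↦ S, and observed summary
statistics S_obs, ABC approximates the posterior π(θ | S_obs) by accepting
simulated parameter values whose statistics land close to S_obs. All
distances are standardized Euclidean:

    d(S, S_obs) = || (S − S_obs) / sd ||₂ ,

with per-statistic standard deviations estimated from a calibration table
(sample sd, ddof = 1). Statistics with zero variance carry no information
about closeness and are excluded from the distance with a logged warning.

## Samplers

**Rejection.** Draws θ i.i.d. from the prior and records every (θ, S)
pair without filtering; retention against a particular observed dataset
happens later, in the estimator. This two-step split lets one large table
serve many observed datasets (the validation harness depends on it).

**Likelihood-free MCMC.** A pilot rejection run of `calibration_size`
simulations fixes (a) the standardization constants, (b) the distance
threshold as the empirical δ-quantile of the pilot distances to S_obs
(linear interpolation between order statistics — the convention must be
pinned for reproducible thresholds), and (c) the chain start as the
closest pilot draw. Proposals are componentwise symmetric uniform
perturbations of half-width `0.05 · φ · prior_range`, reflected at finite
prior bounds (for unbounded priors the range surrogate is six prior
standard deviations). A proposal is accepted iff its simulation falls
within the threshold *and* a uniform draw is below the prior ratio
π(θ′)/π(θ); a failed simulation counts as a rejection. On rejection the
current row is repeated, so the recorded (thinned) rows have the chain's
stationary frequencies and can be fed directly to the estimator. Defaults
δ = 0.1 and φ = 1 follow standard practice for this sampler; the 0.05
half-width constant is configurable because the literature does not pin
it. The acceptance rate is logged, with a warning when it falls below a
floor (default 1%) over a sliding window.

**Population Monte Carlo.** Iterated importance sampling under a strictly
decreasing tolerance schedule. Generation 1 accepts prior draws under the
first tolerance with equal weights. Generation t resamples a previous
particle by weight, perturbs it with a componentwise Gaussian kernel whose
variance is **twice the weighted empirical variance** of the previous
generation (the standard adaptive choice), and accepts under the next
tolerance; the new weight is π(θ) / Σⱼ wⱼ K(θ | θⱼ). The final generation
is returned with weights normalized to sum to one, as a weighted
simulation table; all downstream sums (regression, mixture weights,
p-value) then use those weights.

**Failure policy.** An external simulator that exits nonzero or produces
an unreadable statistics file marks the iteration failed: rejection and
PMC redraw a fresh θ (failures are logged, counted, and capped at a
configurable fraction of attempts, default 50%); MCMC treats the proposal
as rejected. Failed iterations never contribute rows. Each external
iteration runs in its own scratch directory, deleted on success and
retained on failure for debugging. Template tags are square brackets
around the parameter name (`[N]`); values are rendered with 17 significant
digits so a numeric round trip through text is exact.

## GLM posterior estimation

With the J retained pairs (θⱼ, Sⱼ), ordinary (or weighted) least squares
fits S = c₀ + Cθ + ε, ε ~ N(0, Σ_s), with residual covariance divisor
J − p − 1. If Σ_s is not positive definite or its condition number exceeds
1e10, a ridge λI with λ = 1e-8 · tr(Σ_s)/k is added (multiplied by 10
until conditioning is acceptable) and the event logged; a noise-free fit
therefore gets a tiny floor rather than a singular covariance.

The prior truncated to the retention region is represented as an equally
weighted Gaussian mixture centered at the retained θⱼ with a common
diagonal covariance Σ_θ. Gaussian algebra then gives the posterior as a
J-component mixture with common covariance
T = (Cᵀ Σ_s⁻¹ C + Σ_θ⁻¹)⁻¹, component means
mⱼ = T (Cᵀ Σ_s⁻¹ (S_obs − c₀) + Σ_θ⁻¹ θⱼ), and component weights
proportional to N(S_obs; c₀ + Cθⱼ, Σ_s + C Σ_θ Cᵀ) (times the row weight
for weighted tables). Weights are computed in log space and normalized by
log-sum-exp.

**Bandwidth.** Σ_θ is diagonal with per-parameter sd
1.06 · σ̂ᵢ · J^(−1/5) (Scott's rule on the weighted retained sd),
user-overridable. A range-based bandwidth (half the retained range over
J^(1/5)) was considered and rejected: at J ≈ 10³–10⁴ it is roughly three
times wider and visibly over-disperses the posterior — enough to degrade
coverage calibration through pure smoothing rather than through any
property of the estimator.

**Grids and summaries.** Each marginal density is evaluated on a 100-point
grid spanning the retained range extended 5% per side and clipped to the
prior support, then renormalized by the trapezoid rule (so it integrates
to 1 up to floating-point error). The mode is the grid argmax (ties break
toward the smaller value, with a warning). HPD regions add grid cells in
decreasing density order until the target mass is reached and report the
union of contiguous intervals — a single interval for unimodal densities.
Parameters with log10-scale priors are estimated entirely on the log10
scale (fit, grid, mode, HPDI); back-transforming mode and interval
endpoints is monotone.

**Marginal density and model check.** The marginal density of any
statistics vector s is the weighted mixture average of
N(s; c₀ + Cθⱼ, Σ_s + C Σ_θ Cᵀ). The model-fit p-value is the weighted
fraction of retained simulations whose own marginal density does not
exceed (≤, non-strict) that of S_obs; densities are compared in log space
so a far outlier underflows to p = 0 rather than tying at zero. The
p-value is exactly calibrated (uniform under the correct model) when the
retained set is an *exchangeable* prior-predictive sample — e.g. full
retention of a rejection table. Under tight retention it becomes
anti-conservative: the observed vector is by construction the center of
its own retention ball, which pushes its density rank upward. The
calibration study in the test suite therefore uses full retention; treat
small p-values from tightly retained sets as a red flag, but do not read
mid-range values as calibrated probabilities there.

**Bayes factors** are ratios of marginal densities of two models at the
same observed statistics, meaningful when both are computed under the same
statistic transform and comparable retention.

## PLS reduction

Statistics are centered and scaled to unit variance (constant columns are
dropped with a warning), responses (parameters) are standardized
internally, and scikit-learn's NIPALS `PLSRegression` extracts k
orthogonal score directions. The stored transform maps statistics only:
`scores = loadings · ((x − centers) / scales)`, applied identically to
tables and observed vectors. The number of components k is user judgment,
not automated. A Box–Cox pre-transform sometimes used upstream of PLS is
deliberately omitted.

## Coverage validation

M pseudo-observed datasets (θ_true, S) are drawn from prior + simulator;
each is estimated against one shared reference table (no per-record
resimulation). The posterior quantile of θ_true is computed from the grid
CDF — not from the retained sample — so the measure exercises the whole
GLM pipeline. Quantiles are tested against Uniform(0,1) with a two-sided
one-sample KS test (asymptotic Kolmogorov p-value); per-parameter tests
are flagged significant only after Bonferroni correction across the
estimated parameters. Truths falling outside the posterior grid clip to
quantile 0/1 and are counted, not dropped, with the clip count reported.
Bias and RMSE use the posterior mode, on the estimation (log10) scale for
log-scale parameters; empirical HPDI coverage is the fraction of records
whose interval union contains the truth.

## Toy models and what passing tests show

The bundled generators define the test conditions:

* `NormalMeanModel(n_obs=10, sd=1)` — the statistic is the mean of n_obs
  Gaussian draws, so its sampling law N(θ, sd²/n_obs) and the flat-prior
  posterior are exact; used with the U(−5, 5) prior and S_obs = 0.8.
* `LinearGaussianModel` — statistics c₀ + Cθ + ε with Gaussian noise, the
  exact setting the GLM assumes; the conjugate-recovery study uses
  s = 0.5 + 2θ + ε (sd 2), prior U(−10, 10), S_obs = 4.5 (posterior
  N(2, 1)); the model-check study uses 4 statistics with coefficients
  (1, 0.5, −0.5, 0.25) and unit noise.

These toys are analytically tractable and low-dimensional. They do not
emulate the features of real genetic summary statistics — strong
inter-statistic correlation, heteroscedasticity and non-Gaussian noise,
hundreds of statistics per dataset, model misspecification — so passing
tests demonstrate the correctness of the algorithms, not the adequacy of
any particular demographic model. The GLM adjustment in particular is
exact only when the statistics are linear in the parameters with constant
Gaussian noise over the retained region; on real data, retention must be
tight enough for that local approximation to hold.

Problem sizes in the test suite and acceptance script (10⁵-row reference
tables, 10⁵-step chains, 200 pseudo-observed datasets per study, 10
replicate coverage studies) were chosen to make Monte-Carlo error small
relative to the tolerances checked while keeping a full run on one CPU in
minutes; real analyses typically scale these up 10-fold.

## Known limitations

* Rejection's batch fast path and the per-draw path consume the RNG
  differently; results are deterministic per seed but not identical across
  the two paths.
* The MCMC proposal is componentwise uniform with reflection; no
  adaptation or covariance-aware proposals.
* Bayes factors across models with different statistic transforms are not
  comparable; the toolkit does not check this precondition.
* Only per-parameter marginal posteriors are reported; joint surfaces are
  not assembled.
* The model-check p-value calibration caveat above.
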