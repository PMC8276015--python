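# Methods

## The model

`dprelease` releases a sensitive tabular dataset as synthetic records drawn
from the posterior predictive distribution (PPD) of a user-specified
probabilistic model,

```
p(x~ | X) = ∫ p(x~ | θ) p(θ | X) dθ,
```

where the posterior `p(θ | X)` is learned under (ε, δ) differential privacy.
Because the released artifact is a sample from the PPD — never the fitted
parameters — any downstream analysis is post-processing and carries no
additional privacy cost.

The generative model is a finite mixture whose components factorise over
features,

```
p(x | θ, π) = Σ_k π_k Π_j p(x_j | θ_j^(k)),
```

with beta components for continuous features (affinely scaled to the unit
interval using *declared* bounds — bounds are treated as public prior
knowledge and are never estimated from the data, which would leak),
Bernoulli components for binary features and categorical components for
labelled features. Priors: gamma(1,1) on beta shapes, uniform on Bernoulli
probabilities, and flat Dirichlet on every simplex-valued block — both the
categorical parameters and the mixture weights π. (The uniform-prior choice
for π and for the strata marginals is an assumption; any Dirichlet could be
substituted.)

Domain knowledge enters in two ways:

* **Stratification.** An ordered list of discrete variables (e.g. sex,
  end-of-follow-up status) splits the model: each combination of strata
  values gets its own mixture over the remaining features, and the strata
  variables get conditional categorical marginals
  `p(x_sex) p(x_dead | x_sex)`. All strata parameters are estimated inside
  the same privatized objective.
* **Deterministic rules** encode structural zeros. A rule conditions on
  strata values and either pins a feature to a constant (`dead = 0 ⇒
  ard = 0`) or derives it affinely from another feature (`dead = 0 ⇒
  duration = censor − start`). Affected features are *excluded* from the
  conditioned stratum's mixture and reconstructed at sampling time, so a
  rule violation is impossible by construction — no rejection sampling.

The number of components defaults to K = 10 below 20 features and K = 20
from 20 features up, a compromise between resolution and the difficulty of
private learning as the parameter count grows.

## Inference: DPVI without autodiff

The posterior is approximated mean-field: one independent Gaussian per
*unconstrained* coordinate. Transforms: `log` for positive parameters,
`logit` for probabilities, and centred stick-breaking for simplex blocks
(the all-zeros point maps to the uniform simplex). The ELBO is maximised on
the reparameterisation `u = loc + scale · z`:

```
ELBO = E_q[(n/|B|) Σ_{i∈B} log p(x_i | θ(u)) + log p(θ(u)) + log|J(u)|] + H(q).
```

All gradients are analytic and implemented directly in numpy: the data term
is a responsibility-weighted sum of per-feature score functions (Bernoulli:
`x − p`; beta shapes via digamma; categorical and weights via the
stick-breaking chain rule), and the prior/Jacobian/entropy terms have closed
forms. The test suite verifies every gradient path against central finite
differences of the corresponding log-density to ~1e-8 relative error. A
useful identity keeps the per-example gradient matrix small: the log-scale
half of each per-example gradient is the location half with columns scaled
by `scale · z`, so per-example clipping norms and clipped sums factor and
only the location-half matrix is ever materialised.

**Privacy.** DP-SGD with Poisson subsampling at rate q: each example's
gradient (of the data term only) is clipped to L2 norm C; the clipped
gradients are summed and Gaussian noise with standard deviation 2Cσ is
added. The factor 2 is the substitute-adjacency sensitivity — replacing one
record changes the sum by at most two clipped gradients. The prior,
Jacobian and entropy gradients are data-independent and are added after the
noise; the Adam update is post-processing.

**Accounting.** Rényi DP of the subsampled Gaussian mechanism via the
binomial-expansion bound at integer orders 2…512 (plain Gaussian entries
also use fractional orders 1.25–1.75, where the exact `α/(2σ²)` applies),
composed additively over steps and converted with the tight conversion
`ε = RDP(α) + log(1 − 1/α) − log(δα)/(α − 1)`, minimised over the grid.
This conversion matters: the naive `RDP + log(1/δ)/(α−1)` form fails to
audit the classically calibrated single Gaussian (σ = Δ√(2 ln(1.25/δ))/ε)
back to within its own ε. The noise multiplier is calibrated to the budget
by binary search over σ; the round-trip audit ε′ ≤ ε holds by construction
and is re-checked after every fit. `ε = inf` is the documented non-private
sentinel: identical code path, zero noise, empty ledger.

**Training defaults** (all exposed in `TrainingConfig`): T = 2000 steps,
expected batch 512 (q = 512/n), clip C = 2.5, Adam with learning rate 0.05
cosine-annealed to 0.005, single-sample gradient estimates, initial
locations N(0, 1) and initial log-scales −4. The spread-out location
initialisation breaks the symmetry between mixture components, and the
small initial posterior scale keeps early reparameterisation noise from
drowning the data signal; with timid initialisation (scale 0.1, log-scale
−2) and a 1e-3 learning rate the mixture demonstrably undertrains at these
step counts, attenuating within-stratum associations even without privacy
noise. C = 2.5 sits just above the bulk of observed per-example gradient
norms (90th percentile ≈ 2), so clipping bias is mild while the DP noise —
proportional to C — stays small. None of these values is reported by the
motivating study; they are engineering choices of this implementation.

## Sampling

A synthetic record is drawn by: parameter draw θ~ from the posterior
(Gaussian in unconstrained space pushed through the transforms, so support
constraints hold for every draw), strata values from their conditional
marginals, a component from π, each modelled feature from its component
distribution, rule reconstruction, inverse scaling. `theta_mode=
"per_record"` (default) redraws θ~ for every record, propagating posterior
uncertainty into the release; `"single_draw"` holds one θ~ fixed, which
narrows the predictive spread (a tested property). The release defaults to
the original sample size and carries a provenance sidecar (seed, ε, δ,
model hash) — never the fitted parameters.

## Tailored baseline

The comparison arm answers a single query under a uniformly split budget:
with T anticipated queries each gets (ε/T, δ/T), and the uncentered second
moment `(1/n) Σ x xᵀ` of unit-hypercube data is released with symmetrized
Gaussian noise. The Frobenius sensitivity under substitute adjacency is
`2d/n` (since ‖xxᵀ‖_F = ‖x‖² ≤ d); symmetrizing i.i.d. noise halves the
off-diagonal variance exactly as required for the full-matrix sensitivity
bound, and the expected squared Frobenius error is `σ² d(d+1)/2`. A
centered variant (DP mean released separately from half the per-query
budget) is available; uncentered is the default because its sensitivity is
clean. The error necessarily grows with T while the synthetic-data error is
paid once — that is the crossover the evaluation reproduces.

## Evaluation metrics

* **Discovery reproduction.** Poisson regression of event counts with log
  person-time offset (statsmodels GLM, Wald two-sided p-values); a term is
  reproduced when its coefficient is positive *and* p < 0.05, and the
  combined flag requires all prescribed terms. The sign requirement is part
  of the criterion, not an afterthought: a significant association of the
  wrong sign is a wrong discovery.
* **Prevalence-binned MAE.** Coefficients (male and female arms pooled) are
  sorted by the original fit's case count — records with the term indicator
  set and at least one event — with ties broken by name, and split into
  four equal bins, remainder to the last (highest-prevalence) bin. The
  reference curve is the mean inverse case count per bin, the O(1/n) error
  floor of an optimal DP estimator.
* **Bootstrap reproducibility** of the original data quantifies how strong
  the signal was to begin with: resample with replacement, refit, apply the
  same criterion.
* **Frobenius distance** between second-moment matrices of one-hot/unit
  encoded tables for the covariance experiments.

## Synthetic fixtures (what they emulate, what they do not)

The real registers are not public, so validation runs on generators that
emulate their statistical structure with known ground truth.

* **ARD-like cohort** (`generate_ard_like`): two sex strata of 20 000
  subjects each; treatment category (none / OAD / insulin / OAD+insulin at
  prevalences 0.66/0.18/0.08/0.08); uniform entry over a 10-year window,
  censoring at year 15; competing exponential event times with ARD log-rate
  `baseline + Σ coef · treatment indicator` and background mortality
  0.015/yr. The treatment log-rate-ratios are the published original
  estimates of the motivating epidemiological study (males 0.435/1.209/0.582
  for OAD/insulin/OAD+insulin, females 0.657/1.68/0.873); baselines −6.2
  (male) and −7.3 (female) give ≈ 500 and ≈ 190 cases per arm, echoing the
  study's male/female case imbalance. A Poisson person-time regression on
  the generated data recovers the configured coefficients (tested at 3 SE),
  and the original-data discovery-reproduction rate is 1.0 for the male arm,
  so failures downstream are attributable to the release, not the fixture.
  Not emulated: calendar-time rate trends, covariate-dependent censoring,
  the full ten-feature register schema.
* **Carat-like matrix** (`generate_carat_like`): n×d binary install matrix
  from a Gaussian copula with block factors — exact configured marginals,
  tetrachoric within-block correlation (default 0.4), zero across blocks.
  The default d = 96 mirrors the app-subset size of the motivating study;
  the crossover experiment uses d = 32, n = 10 000 as its scaled problem.
* **`generate_mixture_like`**: exact forward samples from a declared model,
  the oracle for parameter recovery.

Passing tests on these fixtures show the pipeline preserves the encoded
structure at realistic effect sizes and sample sizes; they cannot show
anything about features of real registers the generators do not model.

## Study problem sizes

The validation studies run at: 20 repeats × {ε = 1, 2, 4 stratified;
ε = 1 unstratified}, cohorts of 40 000 records, T = 2000 DPVI steps —
roughly ten minutes on one CPU; the crossover study is one DPVI fit on the
10 000 × 32 matrix plus five noise draws per T ∈ {1, 10, 100}. At these
scaled-down sizes the reproduction-rate curve over ε is shallow
(≈ 0.20 → 0.40) and its binomial noise at 20 repeats is visible; the
qualitative orderings (rate nondecreasing in ε, stratified above
unstratified at ε = 1, coefficient error larger in the lowest-prevalence
bin than the highest) are the stable content. The four prevalence bins of
the scaled cohort span mean case counts ≈ 24–86, so the inner bins of the
MAE curve are not individually ordered; the lowest-vs-highest contrast is.

## Numerical choices and degenerate inputs

* Unit-interval scaling clips at 1e-6 from {0,1} so beta log-densities stay
  finite at observed extremes; the inverse map restores interior values
  exactly.
* Unconstrained coordinates are clipped at ±30 before transforms (exp
  overflow guard); stick fractions at [1e-12, 1−1e-12].
* K = 1 degenerates gracefully: the weight block is empty and the mixture
  is a product model.
* Poisson-regression non-convergence/separation (possible on synthetic
  replicas of rare-event arms) is flagged on the report, fails the
  reproduction criterion, and excludes the run from coefficient-error
  averaging rather than being silently swallowed.
* Empty Poisson-subsampled batches contribute noise only — the code path is
  identical, as the privacy analysis assumes.

## Known limitations

* Mean-field Gaussians understate posterior correlations (notably between
  beta shape pairs); the PPD inherits that.
* The subsampled-RDP bound is evaluated at integer orders only; for the
  step counts and rates used here the integer grid changes ε in the third
  decimal at most.
* Mixture-model VI is multimodal; different seeds can land on fits of
  different quality. The validation studies average over 20 seeds for
  exactly this reason.
* No DP hyperparameter tuning: clip norm, learning rate and step count are
  fixed defaults, and tuning them on sensitive data would itself spend
  budget.
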