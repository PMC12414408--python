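# Methods

`phenocal` treats errors in the response variable of mixed-model genetic
evaluations. This note records the models, the numerical choices, and what
the bundled simulators do and do not emulate.

## Models

### Linear measurement-error calibration (continuous traits)

The animal model is y = Xb + Zu + e with u ~ N(0, A σ²u), e ~ N(0, I σ²e),
where A is the pedigree numerator relationship matrix. An error-prone
instrument observes y\* instead of y. Two error structures are supported:

* **Additive unbiased error** y\* = y + ε, ε ~ N(0, I σ²ε). The observed
  response then has covariance ZGZ' + I(σ²e + σ²ε): BLUP remains valid with
  the residual variance inflated by σ²ε (`blup_inflated`).
* **Linear (classical) error** y\*|y = 1α + βy + ε. Substituting the animal
  model gives a "starred" model with u\* = βu, σ²u\* = β²σ²u and
  σ²e\* = β²σ²e + σ²ε. Fitting the mixed-model equations with the starred
  covariances and back-transforming (û = û\*/β̂; fixed effects via the
  projection (X'X)⁻¹X'(X\*b̂\* − 1α̂)/β̂; variance components by the inverse
  of the starred identities) recovers estimates on the true-phenotype scale.

The calibration (α, β, σ²ε) is fitted by ordinary least squares of y\* on y
in a double sample, optionally stratified (the bundled dairy table
stratifies by lactation month × AM/PM milking session); the residual
variance uses the n−2 denominator. The regression direction is classical
(observed on true); Berkson-direction calibration for continuous traits is
out of scope. A negative implied σ²e after subtraction is clamped to zero
with a warning — it indicates the calibration's error variance exceeds the
model residual, which the model cannot represent.

### Misclassification algebra (binary traits)

For a binary trait with true incidence q, an error-prone test with
sensitivity π₁|₁ and specificity π₀|₀ observes incidence
E[q\*] = qπ₁|₁ + (1−q)(1−π₀|₀). The bias of the naive estimator and the
Bernoulli variance shift Δ − 2qΔ − Δ² follow directly. Two equivalent
adjustments invert the bias: by error rates (requires π₁|₁+π₀|₀ ≠ 1, and is
ill-conditioned near that line — the package raises an error at equality and
warns within 0.05 of it), or by reclassification probabilities λ (the
Berkson direction), estimated from validation-set columns or derived from
(π, q) by Bayes' theorem. The two routes agree exactly only when the rates
are mutually consistent at the same q; on real validation counts they agree
approximately (e.g. 10.26% vs 10.24% in the bundled worked example).
Adjusted incidences are clamped to [0, 1] with a flag rather than raising.
No confidence intervals are attached (a delta-method CI is a natural
extension point).

### Liability threshold model with asymmetric misclassification

The observed status y\*ᵢ arises from a latent liability ηᵢ = x'ᵢb + z'ᵢu +
eᵢ with residual variance fixed at 1 and threshold τ; the true status is
yᵢ = [ηᵢ > τ]. Misclassification links y\* to y with possibly unequal
false-positive (1−π₀|₀) and false-negative (1−π₁|₁) rates, giving the
per-record likelihood

    p(y*=1) = π₁|₁ P₁ + (1−π₀|₀)(1−P₁),   P₁ = 1 − Φ(τ − x'b − z'u),

normalized so the two observed classes sum to one; with equal rates it
collapses to the single-parameter misclassification threshold model, and
with perfect rates to the standard threshold model.

**Identification.** τ is fixed from the incidence, τ = Φ⁻¹(1−q̂), using the
observed incidence adjusted for the (known) error rates; fixed-effect
*levels* are not separately identified from τ — location contrasts are.
σ²e = 1 fixes the liability scale, so h² = σ²u/(σ²u+1).

**Sampling.** A blocked Gibbs sampler with data augmentation:

1. Per record, the true status is drawn from its exact two-state posterior
   (prior P₁ from the current linear predictor; likelihood from the error
   rates); the misclassification indicator is δᵢ = [yᵢ ≠ y\*ᵢ]. The
   liability is then drawn from N(x'b+z'u, 1) truncated to the side of τ the
   drawn status implies, via the one-sided inverse-CDF form (numerically
   stable far from the threshold; validated against `scipy.stats.truncnorm`).
2. Fixed effects: conjugate normal update with a proper N(0, σ²b = 1) prior.
   A flat prior is **not** usable here: integrating the probit likelihood
   over a flat b grows like σu^p (p = number of levels), making the joint
   posterior of (b, σ²u) improper — empirically the chain's σ²u drifts
   without bound, even when started at the generative values. σ²b = 1
   matches the scale on which fixed-effect levels are simulated and is
   user-overridable.
3. The additive-value block is drawn jointly. With the one-time generalized
   eigendecomposition Z'Z W = A⁻¹ W diag(θ) (normalized W'A⁻¹W = I), the
   full conditional of v = W⁻¹u has diagonal precision θ + 1/σ²u for any
   σ²u, so a sweep costs two matrix–vector products instead of a Cholesky
   factorization; u'A⁻¹u = v'v falls out for free.
4. σ²u has a scaled-inverse-chi-square prior (default ν = 4 with scale set
   from a prior h² of 0.25, i.e. S = h²/(1−h²) on the liability scale) and a
   conjugate update.
5. Error rates, when estimated rather than fixed, get Beta(2, 1) full
   conditionals from the current (y, y\*) cross-counts, rejection-truncated
   to π₁|₁+π₀|₀ > 1 to prevent label switching.

Posterior summaries report mean/SD/central 95% intervals, bulk ESS and a
split-chain Rhat per scalar parameter, the posterior incidence (mean imputed
true-positive fraction) and misclassification fraction, and
Rao-Blackwellized posterior means of b and u (averaged conditional means,
which have less Monte-Carlo noise than averaged draws).

Animals without phenotypes (e.g. parents) can be marginalized out of A
before fitting — the likelihood is unchanged — and their posterior-mean
additive values recovered afterwards as A_po A_oo⁻¹ û_o; the chain then runs
on the phenotyped block only.

Chain defaults are 100,000 iterations, 20,000 burn-in, thinning 10. The test
suite and the replicate studies use reduced chains (20,000 / 4,000 / 10),
which for the bundled 643-cow design give bulk ESS of roughly 70–130 for
σ²u — adequate for the interval and ordering checks performed there.

### Linear Gibbs sampler

The same blocked scheme fits the linear animal model on continuous records,
or on 0/1 records read as a linear (observed-scale) model; both variance
components are then sampled, with the prior scales splitting the phenotypic
variance according to the prior h². Fixed effects keep a flat prior here —
with a Gaussian likelihood on observed data the posterior is proper.

## Simulators

The default `SimConfig` emulates a dairy study: 125 unrelated sires × 477
unrelated dams, 643 phenotyped cows each assigned a uniformly random sire
and dam (paternal half-sib structure), a 10-level fixed effect with level
values drawn standard normal and uniform level assignment, additive values
with covariance Aσ²u realized exactly by the pedigree recursion (founders ~
N(0, σ²u); offspring = parent average + Mendelian-sampling deviate with
variance σ²u(0.5 − 0.25(F_s+F_d))), residuals N(0, 1), and
σ²u = h²/(1−h²)·σ²e with h² = 0.4.

The binary trait is the latent liability thresholded at its empirical 80th
quantile with the ascending-rank ⌊0.8n⌋ / strictly-greater convention, so
643 records give exactly 129 positives (incidence 20.06%) for every seed.
Note the threshold *value* depends on the latent scale: with the fixed
effect contributing ≈1 unit of variance the realized τ sits near 1.4; only
the incidence, not τ itself, is scale-free, and all downstream analyses key
on the incidence. Misclassification is injected by independent Bernoulli
flips (false-positive rate on the negatives, false-negative rate on the
positives); the equal-rate scenario uses 0.15/0.15, the unequal one
0.2/0.1.

Replicated studies in the test suite redraw *everything* per replicate —
pedigree, fixed effects, genetic and residual values, misclassification —
so that conclusions about estimator behaviour are not conditioned on a
single pedigree realization; with ~5 cows per sire the realized information
about σ²u varies noticeably between pedigree draws.

What the simulator does **not** emulate: a real multi-generation pedigree
(relationships among parents, long-tailed sire usage), selection,
non-random mating, herd-year structure, or covariate-dependent error rates.
Consequences: the synthetic half-sib design carries relatively little
information about σ²u per record, so posterior summaries at n = 643 are
prior-influenced and replicate-to-replicate variable; passing tests
demonstrate correctness of the algebra and the samplers, not field-scale
power.

## Numerical choices

* A and A⁻¹ are dense (tabular recursion; Cholesky inversion); intended
  scale ≤ ~5,000 animals. Unknown parents are unrelated, non-inbred
  founders. Labels are opaque strings; matrices carry their id ordering.
* Mixed-model equations: dense Cholesky with a one-shot 1e-8·mean-diagonal
  jitter retry; the condition number of the coefficient matrix is reported.
  No estimability constraints are imposed on fixed levels — contrasts, not
  levels, are identified, and solutions are reported as-is.
* Truncated-normal draws clip tail probabilities at 1e-300 (and the
  two-state posterior clips P₁ into [1e-12, 1−1e-12]) so degenerate rates
  and extreme linear predictors remain finite.
* All generators and samplers are pure functions of (configuration, seed)
  via `numpy.random.default_rng`; identical seeds reproduce chains
  bit-for-bit. CLI artifacts embed the seed and a config hash.
* Dichotomization raises on ties at the threshold (relevant only for
  integer-valued latents, which the simulators never produce).

## Known limitations

* The misclassification model assumes record-independent, covariate-free
  error rates known exactly or exchangeable a priori.
* Estimating (π₁|₁, π₀|₀) jointly with τ free is not identified; the package
  therefore fixes τ from the incidence before rate estimation.
* Multi-category (ordinal) thresholds, genomic relationship matrices, REML,
  and sire models are out of scope.
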