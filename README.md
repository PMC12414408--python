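# phenocal

Phenotype-error calibration for genetic evaluations.

High-throughput and unsupervised phenotyping (sensor streams, unofficial
tests, predicted rather than measured yields) feeds genetic evaluation
pipelines with response variables that carry measurement error. `phenocal`
implements the statistical machinery a quantitative geneticist needs to
recognize, quantify, and correct such errors, for both continuous and binary
traits:

* **Linear measurement-error calibration** (continuous traits). Under the
  classical error model *y\* = α + βy + ε*, a double sample fits
  (α, β, σ²ε) and back-adjusts estimated effects and variance components:
  û = û\*/β̂, σ̂²u = σ̂²u\*/β̂², σ̂²e = (σ̂²e\* − σ̂²ε)/β̂². BLUP under
  additive error is solved with the residual variance inflated to
  σ²e + σ²ε (`blup_inflated`).
* **Misclassification algebra** (binary traits). From a double-sampling 2×2
  validation table: sensitivity π₁|₁ and specificity π₀|₀, reclassification
  (predictive) probabilities λ₁|₁ and λ₀|₀, the naive-incidence bias
  E[q\*] − q = q(π₁|₁+π₀|₀−2) + (1−π₀|₀), and the two inverse adjustments
  q̂ = (q̂\* − (1−π₀|₀))/(π₁|₁+π₀|₀−1) and
  q̂ = q̂\*(λ₁|₁+λ₀|₀−1) + (1−λ₀|₀).
* **A liability threshold animal model with asymmetric misclassification.**
  The observed status relates to the latent liability η = x'b + z'u + e
  (residual variance fixed at 1, threshold τ = Φ⁻¹(1−q)) through
  p(y\*=1) = π₁|₁P₁ + (1−π₀|₀)(1−P₁) with P₁ = 1−Φ(τ−x'b−z'u). A Gibbs
  sampler augments the data with per-record true statuses (misclassification
  indicators δᵢ) and liabilities; error rates can be fixed or estimated with
  Beta priors. Heritability is reported on the liability scale,
  h² = σ²u/(σ²u+1).
* **Pedigree machinery**: the numerator relationship matrix **A** (tabular
  method, inbreeding on the diagonal) and its inverse.
* **Simulators** for pedigreed binary/continuous traits, misclassification
  injection, paired calibration samples, and double-sampling designs.

## Worked example: calibrating an error-prone binary diagnosis

2,580 animals; 980 form an internal validation set scored by both the
error-free and the error-prone method, 1,600 are scored by the error-prone
method only:

```python
from phenocal import (ValidationCounts, rates_from_validation,
                      reclass_from_validation, double_sampling_report)

counts = ValidationCounts(n00=840, n01=40, n10=3, n11=97)
report = double_sampling_report(counts, test_counts=(1375, 225))
for k in ("sensitivity", "specificity", "lambda11", "lambda00",
          "observed_incidence", "validation_incidence",
          "adjusted_incidence_by_rates", "adjusted_incidence_by_reclass"):
    print(f"{k:30s} {report[k]:.4f}")
```

prints

```
sensitivity                    0.9700
specificity                    0.9545
lambda11                       0.7080
lambda00                       0.9964
observed_incidence             0.1403
validation_incidence           0.1020
adjusted_incidence_by_rates    0.1026
adjusted_incidence_by_reclass  0.1024
```

The error-prone test sees 14.0% positives, but after inverting its known
error rates the incidence estimate drops to 10.3% — in line with the 10.2%
seen in the error-free validation subset. Both adjustment routes (via
sensitivity/specificity and via reclassification probabilities) agree.

The same from the command line:

```bash
phenocal adjust-incidence --counts examples/double_sampling_counts.csv
```

## Worked example: a misclassified binary trait with pedigree

```python
import numpy as np
from phenocal import (SimConfig, simulate_trait, dichotomize,
                      inject_misclassification, ErrorRates,
                      adjust_incidence_by_rates)

trait = dichotomize(simulate_trait(SimConfig(seed=1)), 0.8)
print(f"true incidence {100*trait.incidence:.2f}%")       # 20.06%
rng = np.random.default_rng(1)
trait = inject_misclassification(trait, (0.2, 0.1), rng)  # fp, fn rates
print(f"observed incidence {100*trait.observed_incidence:.2f}%")  # ~34%
adj = adjust_incidence_by_rates(trait.observed_incidence,
                                ErrorRates(sensitivity=0.9, specificity=0.8))
print(f"adjusted incidence {100*adj.q:.2f}%")             # ~20%
```

With seed 1 this prints `20.06%`, `30.64%`, `15.20%`: thresholding 643
latent liabilities at their empirical 80th quantile gives exactly 129
positives; injecting a 0.2 false-positive / 0.1 false-negative rate inflates
the observed incidence (expected value ≈34%); inverting the known error
rates points back toward the true ≈20%. A single replicate of 643 animals is
noisy (the adjusted estimate has a binomial standard error of ≈2.7 points);
averaging over 20 seeds recovers ≈20.1% (`scripts/acceptance.py` does
exactly this). The misclassification-aware threshold model is then fitted with
`gibbs_threshold` (see `docs/methods.md`), or from the shell with
`phenocal fit-threshold --sensitivity 0.9 --specificity 0.8 ...`.

## Layout

| module | contents |
|---|---|
| `phenocal.pedigree` | pedigree parsing, **A** and **A**⁻¹ |
| `phenocal.calibration` | linear error model fitting and back-adjustment |
| `phenocal.misclassification` | sensitivity/specificity, reclassification, incidence adjustment |
| `phenocal.mixed_model` | design matrices, inflated-residual BLUP, linear Gibbs sampler |
| `phenocal.threshold` | misclassification-aware liability threshold model |
| `phenocal.simulate` | pedigreed trait / double-sampling simulators |
| `phenocal.datasets` | bundled dairy daily-milk-yield calibration table |
| `phenocal.cli` | `phenocal` command-line interface |
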