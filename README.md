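# seqnz — sequential neutral-zone diagnosis from longitudinal biomarkers

`seqnz` is a data-driven framework for prospective sequential diagnosis:
instead of prescribing a fixed panel of diagnostic measurements, it decides
— separately for every patient, after every measurement — whether the
evidence already supports a definitive classification or whether one more
measurement is worth its cost, and if so, which one. The motivating
application is prognosis of conversion from mild cognitive impairment (MCI)
to manifest Alzheimer's disease from four markers of very different cost
and accuracy: an MRI-derived atrophy score (SPARE-AD), the invasive but
sensitive CSF amyloid-beta 1-42 assay, and two cheap cognitive tests (MMSE,
RAVLT), each measured repeatedly at irregular visit times.

## The model and the rules

A longitudinal Gaussian discriminant model supplies everything:

* **prevalence model** — logistic regression of the class label z
  (1 = converter) on baseline age a: `P(z=1|a) = expit(λ₀ + λ₁a)`;
* **marker model** — a stacked linear mixed-effects model: marker h at time
  t has class-conditional mean `β₁ₕ^(z) + β₂ₕ^(z)a + β₃ₕ^(z)t`, a shared
  per-subject random intercept and slope per marker (joint covariance Ψ),
  and marker residual variance ρₕ, so any measurement subset y is Gaussian,
  `y | z ~ N(Xβ^(z), ZΨZ' + R)`, with common covariance across classes in
  the default linear variant.

Bayes' rule turns observed values into a posterior converter probability π̂.
Each candidate measurement is scored by its **expected cost reduction**:
the drop in expected misclassification cost of the forced choice
(prospective false-positive/false-negative rates under the candidate's
predictive distribution — a normal-CDF closed form in the linear variant,
Monte Carlo in the quadratic one) minus its acquisition cost and the cost
of waiting. A positive score puts the decision in the **neutral zone**: the
*greedy* rule then acquires the earliest worthwhile measurement, the
*exhaustive* rule the most valuable one; skipped earlier visits are
forfeited. With misclassification cost 100 and acquisition cost x, a
measurement is taken exactly when the expected accuracy gain exceeds x/100.

Because the real cohorts (ADNI, AIBL) are access-restricted, the package
ships a seeded synthetic-cohort generator with exactly the model's
generative structure, used by every test and experiment.

## Worked example

```python
import numpy as np
from seqnz import (CostSpec, LongitudinalDiscriminantModel, default_preset,
                   score_strategy, simulate_cohort, standard_strategies)

cohort = simulate_cohort(default_preset("adni_like", seed=1))   # n = 612
train, test = cohort.records[:412], cohort.records[412:]

model = LongitudinalDiscriminantModel(train)
result = model.fit()                 # ML: profiled GLS + L-BFGS on (Ψ, ρ)
print(result.summary())              # fixed effects ± SE, ρ, prevalence

costs = CostSpec.from_tuple(2, 2, 4, 1)   # time 2; MRI 2; CSF 4; cognitive 1
for name in ("sequential_greedy", "fixed_multivariate_long_all"):
    fn = standard_strategies(result.theta, costs, seed=0)[name]
    s = score_strategy([fn(r) for r in test], test, costs, name=name)
    print(f"{name:32s} acc={s.accuracy:.3f} n_obs={s.mean_n_obs:5.1f} "
          f"followup={s.mean_followup_time:.2f}y total_cost={s.mean_total_cost:.1f}")
```

Output from this exact script:

```
sequential_greedy                acc=0.935 n_obs=  2.2 followup=0.13y total_cost=12.5
fixed_multivariate_long_all      acc=0.955 n_obs= 15.4 followup=2.59y total_cost=32.7
```

Reading: the adaptive strategy reaches within 0.02 of the accuracy of
using *all* ~15 measurements per subject while acquiring ~2 of them and
deciding about seven weeks after baseline — so its total prescribed cost
(errors + acquisitions + waiting) is less than half that of the
use-everything panel. `result.theta` carries the fitted parameters;
`SequentialTrace` objects record every posterior, candidate score and
selection for audit (`seqnz.io.write_traces_jsonl`).

The same pipeline is available from the shell:

```sh
seqnz simulate --preset adni_like --seed 1 --out cohort.csv
seqnz fit --cohort cohort.csv --out theta.json --cv-k 20
seqnz sequential --theta theta.json --cohort cohort.csv --rule exhaustive \
      --costs 2,2,4,1 --traces traces.jsonl --summary summary.csv
seqnz compare --theta theta.json --cohort cohort.csv --out grid.csv
```

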