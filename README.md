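# dprelease

Differentially private data release via probabilistic modelling: fit a
user-specified stratified mixture model to sensitive tabular data with
DP variational inference (DPVI), then release a synthetic dataset sampled
from the posterior predictive distribution (PPD). Built for data holders —
registries, cohort studies, app-telemetry projects — who want to publish an
anonymized *data twin* that still supports the statistical analyses the
original data were collected for, instead of answering one DP query at a
time until the budget runs out.

## The idea

For data `X` and a model `p(X | θ)`, the release is a sample from

    p(x̃ | X) = ∫ p(x̃ | θ) p(θ | X) dθ,

with the posterior learned under (ε, δ)-DP, so the synthetic data — and
every analysis run on them afterwards — inherit the guarantee by
post-processing. The model is a mixture with independent features within
components,

    p(x | θ, π) = Σₖ πₖ Πⱼ p(xⱼ | θⱼ⁽ᵏ⁾),

over beta / Bernoulli / categorical feature families, and the modelling
layer is where prior knowledge goes: stratify by known effect modifiers
(`p(x_sex) p(x_dead | x_sex) Σₖ πₖ …`) and declare structural zeros as
deterministic rules (a living subject cannot have a cause of death; an
uncensored follow-up is determined by its start date). Inference is DP-SGD
on the reparameterized ELBO — per-example gradients clipped to norm C,
Gaussian noise of std 2Cσ under substitute adjacency — with a Rényi-DP
accountant calibrating σ to the budget and auditing the spent ε afterwards.
Utility is judged by whether the *discoveries* survive: refit the original
study's Poisson rate regression on the synthetic data and require every
term positive and significant (p < 0.05).

## Worked example

Simulate a diabetes/alcohol-related-death (ARD) style cohort with known
ground truth, fit the stratified model at ε = 1, δ = 1e-6, and check which
discoveries survive:

```python
from dprelease import BayesianDataRelease, datasets
from dprelease.experiments import ard_regression
from dprelease.evaluation import discovery_reproduced

cfg = datasets.ArdLikeConfig()                      # 20 000 subjects per sex
records, truth = datasets.generate_ard_like(cfg, seed=7)
model = BayesianDataRelease(records, datasets.ard_schema(cfg),
                            strata=["sex", "dead"],
                            rules=datasets.ard_model_config(cfg)["rules"])
res = model.fit(epsilon=1.0, delta=1e-6, seed=42)
print(res.summary())
synth = res.sample(seed=43)
```

```
Bayesian DP data release
============================================================
records: 40000    features: 6    components K: 10
strata: ['sex', 'dead']    cells: 4
budget: epsilon=1, delta=1e-06    spent: 0.9998
model hash: 2d9e6b7955dd
final ELBO estimate: -85346.5
posterior mean marginal p(sex | earlier strata):
    0.489  0.511
posterior mean marginal p(dead | earlier strata):
    0.839  0.161
    0.852  0.148
cell (0, 0): top weights 0.380  0.245  0.122  0.098  0.068  0.053
...
```

The audited privacy spend (0.9998) stays inside the budget, and the fitted
strata marginals match the cohort (≈ 16% deceased). Rerunning the male-arm
rate regression on original vs synthetic data:

```
male-arm Poisson coefficients (original vs synthetic):
  oad          +0.554 (0.0000)   +0.828 (0.0000)
  insulin      +1.206 (0.0000)   +0.868 (0.0000)
  oad_insulin  +0.410 (0.0115)   +0.205 (0.2093)
discovery reproduced: False {'oad': True, 'insulin': True, 'oad_insulin': False}
```

At strict privacy the two common treatment effects survive with the right
sign and significance, while the rarest subgroup (OAD+insulin, ~50 cases)
loses significance — rare signals are exactly what DP protects hardest,
and what loosening ε (or encoding more prior knowledge) buys back. Every
synthetic record satisfies the structural rules by construction: no living
subject carries an ARD flag.

The same pipeline is scriptable:

```
dprelease simulate --kind ard --out ard.csv
dprelease release --data ard.csv --model-config model.yaml \
    --epsilon 1.0 --delta 1e-6 --seed 42 --out synthetic.csv
dprelease audit --manifest synthetic.csv.manifest.json
dprelease baseline-covariance --data installs.csv --epsilon 1.0 -T 10 --out cov.csv
dprelease evaluate --original ard.csv --synthetic synthetic.csv \
    --model-config model.yaml --analysis-config analysis.yaml --out report.json
```

with model configs in YAML (see `dprelease.cli_io` for the schema):

```yaml
features:
  - {name: sex,       kind: binary}
  - {name: treatment, kind: categorical, labels: [none, oad, insulin, oad_insulin]}
  - {name: start,     kind: continuous, bounds: [0.0, 10.0]}
  - {name: duration,  kind: continuous, bounds: [0.0, 15.0]}
  - {name: dead,      kind: binary}
  - {name: ard,       kind: binary}
strata: [sex, dead]
rules:
  - when: {dead: 0}
    set: {ard: 0}
    derive:
      duration: {source: start, scale: -1.0, offset: 15.0}
```

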