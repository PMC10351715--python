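# bayesmmi

Bayesian multimodel inference for tumor cell-state population dynamics.

Small cell lung cancer tumors mix discrete transcriptional subtypes
(A, N, A2, Y).  Given only each cohort's subtype-proportion summary
(mean and variance across replicate samples), many mechanistic models —
which subtypes exist, which seed the tumor, which transition into which,
which modulate the others' growth — can explain the data.  `bayesmmi` is
for modelers who want to weigh *all* of them instead of picking one:

* **Enumerate** the biologically constrained space of candidate ODE
  models (5,891 under the calibrated preset, out of a naive
  15 × 2^44 ≈ 2.6 × 10^14).
* **Fit** each candidate by nested sampling: the marginal likelihood
  (evidence) `P(D|M_k) = ∫ P(D|θ,M_k) P(θ|M_k) dθ` is estimated with a
  bundled, seeded sampler; steady-state subtype proportions are scored
  against the cohort summary with a Beta/exponential composite
  likelihood.
* **Infer across models**: posteriors `P(M_k|D) ∝ P(D|M_k) P(M_k)`,
  95% and relative-likelihood (Bayes factor ≤ √10) confidence sets,
  hypothesis posteriors `P(H_i|D)` with bias-avoiding per-model priors
  `P(M_k|H_i) = P(H_i)/|{M ∈ H_i}|`, posterior odds `p/(1-p)`, Bayesian
  model averaging of parameters, ANOVA + Tukey HSD comparison of
  averaged distributions, and conservative consolidation (closest
  posterior to the 0.5 prior).
* **Contrast with information criteria**: AIC/AICc, Akaike weights
  `w_k = e^{-Δ_k/2}/Σ_r e^{-Δ_r/2}`, per-variable sums of weights (SW),
  and BIC probabilities — including the didactic 16-model linear
  regression demonstration in which SW overstates support for an
  uncorrelated predictor while its Bayesian posterior drops well below
  the prior.

See `docs/methods.md` for the model, priors, sampler and design choices.

## Worked example

Enumerate the hypothesis space, generate a synthetic cohort, fit two
candidate models and rank them:

```sh
$ bayesmmi enumerate --out candidates.csv
5891 candidate models -> candidates.csv

$ bayesmmi synth --preset tko --seed 4 --out tko.csv --summary-out tko_summary.csv
20 samples -> tko.csv
summary -> tko_summary.csv

$ bayesmmi fit --data tko_summary.csv --store store --max-models 3 --n-live 60 --seed 2
fitted 2 candidates into store

$ bayesmmi rank --store store --out rank.tsv
ranked 2 models -> rank.tsv
```

`rank.tsv` then holds one row per fitted model:

```
model_id          prior  log_evidence  posterior  in_95_set  in_relative_likelihood_set
5256fb160ac4fd40  0.5    -8.170        0.994      True       True
426a335fa549da82  0.5    -13.321       0.006      False      False
```

The first model's evidence is e^{5.15} ≈ 172 times the second's, so it
carries 99.4% of the posterior mass and is the only member of either
confidence set.  (One of the three requested candidates — the homogeneous
single-A baseline — cannot be scored against this multi-subtype cohort
and is recorded as unscorable.)

The regression demonstration prints the per-variable comparison:

```sh
$ bayesmmi regression-demo --seed 1
variable       SW  prior  posterior
      x1 0.999999    0.5   0.999999
      x2 0.253370    0.5   0.149372
      x3 0.253788    0.5   0.103744
      x4 0.253395    0.5   0.083105
```

x1 correlates perfectly with the response: both pathways include it with
certainty.  x4 is pure noise: its Bayesian posterior falls from the 0.5
prior to ~0.08, while the sum of AICc weights stays at ~0.25 — the
overstatement the demonstration is about.

As a library:

```python
from bayesmmi.model_space import enumerate_candidates, paper_config
from bayesmmi.inference import SamplerConfig, fit_candidate
from bayesmmi.synthetic import TKO_LIKE, sample_cohort, summarize_cohort

summary = summarize_cohort(sample_cohort(TKO_LIKE))
candidates = enumerate_candidates(paper_config())
result = fit_candidate(candidates[5], summary, SamplerConfig(n_live=100, seed=0))
print(result.logz, result.logz_err)
```

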