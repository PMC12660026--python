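# tdcm

Bayesian transition diagnostic classification models with Pólya-gamma Gibbs
sampling.

A diagnostic (cognitive-diagnosis) measurement model links binary item
responses to latent binary attribute profiles through a logistic model with
intercepts, positive main effects, and optional interaction terms (driven by
a Q-matrix). Longitudinal change is modeled structurally: each attribute's
full mastery trajectory across `T` time points is one of `2**T` discrete
transition types, governed by a per-attribute multinomial logistic regression
on respondent covariates (the never-mastered trajectory is the zero-constrained
baseline). Both logistic layers are estimated jointly by a three-step Gibbs
sampler made conjugate through Pólya-gamma data augmentation.

## Layout

- `tdcm.model_core` — domain types (Q-matrix, profile/trajectory codecs,
  item and transition design matrices, response data) and the forward
  probability functions.
- `tdcm.pg_augmentation` — Pólya-gamma draws (Devroye-type rejection
  sampler, numba-accelerated when available, with a slow series-based
  reference sampler for validation), the conjugate Gaussian update, and a
  tail-stable truncated-normal sampler.
- `tdcm.gibbs_engine` — the hierarchical sampler: exact categorical profile
  updates, class-aggregated truncated-normal item updates, and
  multinomial-logit transition updates with an inner `m`-sweep loop.
- `tdcm.simulator` — synthetic-data designs (four canonical recovery-study
  settings), dataset generation, and simulate-and-refit coverage studies.
- `tdcm.diagnostics` — posterior-predictive match percentage, per-item AUC
  and Brier score, conditional transition-probability tables, and trace
  summaries.
- `tdcm.cli` — the `tdcm` command-line tool.

## CLI

```sh
# generate a synthetic dataset (design setting 1-4)
tdcm simulate --config sim.yaml --out data/ --seed 3

# fit: writes draws.csv, summary.json, gof.json
tdcm fit --responses data/responses.csv --qmatrix data/qmatrix.csv \
         --covariates data/covariates.csv --config fit.yaml --out fit/ --seed 1

# coverage study (simulate-and-refit replicates)
tdcm recover --config recover.yaml --out recovery/ --seed 2
```

Example config:

```yaml
simulate:
  setting: 1        # 1: treatment only, 2: +interactions, 3: +covariates, 4: T=3
  I: 800
model:
  covariate_map: {2: [treatment]}   # covariates per transition type
sampler:
  M: 5000
  burn: 1000
  sigma_lambda: 2.0
  sigma_gamma: 2.0
recover:
  n_replicates: 20
```

File formats are plain CSV: responses with columns `item<j>_t<t>` (0/1, no
missing cells), the Q-matrix with one row per item and one 0/1 column per
attribute, and a numeric covariate table with one row per respondent.

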