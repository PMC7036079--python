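# biosimpk

Population pharmacokinetics of intravenously infused biologics, built for
biosimilar-vs-reference comparisons on sparse sampling designs. The package
implements the full analysis workflow as tested, scriptable Python:

- **`pk_model`** — closed-form two-compartment (and degenerate
  one-compartment) kinetics with zero-order infusion input and linear
  superposition over doses; multiplicative covariate models (power terms for
  continuous covariates, fractional shifts for categoricals, ratio terms for
  a two-level drug-product effect); exponential subject-level random effects.
- **`nlme_engine`** — first-order conditional estimation with η–ε
  interaction (FOCE-I): vectorized Newton solves for the empirical Bayes
  modes, a Woodbury-based objective, quasi-Newton outer optimization on
  transformed parameters, inverse-Hessian standard errors, shrinkage and CV%.
- **`trial_simulator`** — synthetic trials emulating a two-arm,
  weight-normalized (15 mg/kg q21d) infusion study: per-cycle troughs,
  post-infusion peaks at cycles 1 and 5, end-of-treatment sample, LLOQ
  censoring, reproducible per-subject random substreams.
- **`dataset_io`** — NONMEM-dialect rectangular event tables (CSV), with
  the pre-modeling exclusion rules (first-cycle pre-dose > 2×LLOQ;
  post-dose below-LLOQ discarded) and a full audit trail.
- **`scm`** — stepwise covariate modeling: forward inclusion at α = 0.05,
  backward elimination at α = 0.001, forced terms, overparameterization
  check, deterministic traces.
- **`model_qualification`** — CWRES/IWRES residuals, the |residual| > 6
  outlier rule with a 20% influence check, subject-resampling bootstrap
  CIs, and visual predictive checks with simulated percentile bands.
- **`cli`** — a `biosimpk` command running the whole pipeline
  (simulate → fit → scm → outliers → bootstrap → vpc → report) into a
  reproducible run directory.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria, including the
long-running recovery, discrimination and bootstrap-coverage experiments
(the whole suite takes roughly 20 minutes on one CPU).

## CLI

```sh
biosimpk all --profile smoke --seed 1 --out runs/demo
```

Profiles: `smoke` (20 subjects), `recovery` (100 subjects), `full-scale`
(705 subjects, 1000 bootstrap replicates and VPC trials). Any setting can
be overridden with a YAML file passed via `--config`; every artifact
records the SHA-256 of the resolved configuration. Individual stages are
available as subcommands (`simulate`, `fit`, `scm`, `outliers`,
`bootstrap`, `vpc`, `report`).

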