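# File formats

All interchange files are plain text (CSV, YAML, JSON).

## Ratings CSV (canonical data interchange)

Long format, one row per observed (ratee, item, rater) triple:

| column | type | meaning |
|---|---|---|
| `ratee` | string/int | opaque ratee id |
| `item`  | string/int | opaque item id |
| `rater` | string/int | opaque rater id |
| `score` | 0 or 1 | the dichotomous rating |

The reader rejects duplicate (ratee, item, rater) triples and non-binary
scores, naming the offending line. External ids are mapped to dense
0-based indices (numeric ids in numeric order, otherwise lexicographic);
the mapping is kept on the loaded table (`RatingsTable.id_maps`). Long
format is used rather than a 3-D array dump because incomplete rating
designs make the ratee × item × rater array ragged.

## Q-matrix CSV

Header row of attribute names, then one 0/1 row per item. Every row and
every column must contain at least one 1.

## Truth sidecars (written by `simulate`)

- `truth_profiles.csv` — `ratee` index column, then one 0/1 column per
  attribute (`A1..AK`): the generating mastery profiles.
- `truth_theta.csv` — the underlying multivariate-normal ability draws.
- `truth_xi.csv` — latent ideal categories of HRM-generated data
  (ratee × item; only with shared categories).

## Run configuration YAML

```yaml
model: facets          # standard | facets | hrm
cdm: saturated         # saturated | dina
qmatrix: path/q.csv
ratings: path/ratings.csv
output_dir: out
seed: 7
schedule: {n_chains: 2, n_iterations: 10000, burn_in: 5000, thin: 10}
priors:  {item_sd: 4.0, eta_sd: 1.0, phi_sd: 1.0, log_psi_sd: 4.0}
```

Every CLI run logs its fully resolved configuration (including defaults)
to stderr and writes it back to `config.yaml`, so runs can be reproduced
bit-for-bit.

## Posterior summary JSON (`results.json`)

- `model`: `{rater_model, cdm}`
- `seed`: integer seed of the run
- `parameters`: per parameter name → `{eap, sd, rhat}`. Names:
  `lambda[j,0]` (intercept of item j), `lambda[j,1,Ak]` (main effect of
  attribute k), `lambda[j,2,AkxAv]` (two-way interaction),
  `lambda[j,top]` (DINA conjunctive weight), `eta[r]`, `phi[r]`, `psi[r]`.
- `raters`: per rater id → `{severity, severity_sd, variability,
  variability_sd}` (the per-rater summary table layout).
- `acceptance`: mean Metropolis acceptance rates per block.
- `max_rhat`, `n_free_params`
- `mastery_probs`: N × K posterior attribute-mastery probabilities.

## Draws CSV (`--save-draws`)

`chain, draw`, then one column per structural parameter; retained
(post-burn-in, thinned) draws only.

## Study reports (`replicate`)

- `study<k>_parameters.csv` — `condition, model, parameter, generating,
  bias, rmse` (one row per parameter per fitted model per condition).
- `study<k>_recovery.csv` — `condition, model, min, max, mean, sd`
  (whole-pattern recovery % across replications),
  `mean_attribute_recovery`, `mean_posterior_recovery` (mean posterior
  probability of the true pattern), `mean_rmse`.
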