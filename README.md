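# ratercdm

Cognitive diagnosis models with rater effects: simulate, fit, and evaluate
the **facets-CDM** and the **HRM-CDM**, alongside rater-free standard-CDM
comparators.

Cognitive diagnosis models (CDMs) classify each examinee into a binary
mastery profile α ∈ {0,1}^K over K skills, driven by a Q-matrix that says
which skills each item requires. When items are constructed responses —
essays, spoken tasks, clinical checklists — human raters score them, and
raters differ: some are systematically severe, some erratic. A profile
estimated while ignoring rater effects confounds the examinee with
whoever happened to mark them. This package is for psychometricians and
applied measurement researchers who need diagnostic classification from
rater-mediated dichotomous data.

## Models

Both models use the log-linear cognitive diagnosis model (LCDM) as the
measurement kernel,

```
logit P(X_j = 1 | α) = λ_j0 + Σ_k λ_jk α_k q_jk + Σ_{k<v} λ_jkv α_k α_v q_jk q_jv + …
```

with positive main effects (mastery never hurts) and the DINA model as
the constrained special case (intercept + one conjunctive term, i.e.
guessing g_j and slip s_j).

- **Facets-CDM** — rater severity enters the logit additively:
  `logit P(X_ijr = 1) = λ_j0 − η_r + kernel(α_i)`, with mean(η) = 0 for
  identification. Every rating is an independent measurement, so more
  raters mean better measurement.
- **HRM-CDM** — a two-stage hierarchical rater model: a latent *ideal*
  category ξ_ij follows the LCDM, and each rater reads it through a
  signal-detection kernel `P(k | ξ) ∝ exp(−(k − (ξ − φ_r))² / 2ψ_r²)`,
  normalized over k ∈ {0,1}; φ_r is severity, ψ_r rating variability.
- **Standard CDM** — the rater-free baseline, fit either with raters as
  *virtual items* or as *virtual examinees* (posterior-averaged copies).

Estimation is Bayesian via a self-contained Metropolis-within-Gibbs
sampler (weakly informative normal priors, positivity by truncation,
zero-mean severity constraint, Gelman–Rubin convergence monitoring, EAP
point estimates). `docs/methods.md` documents the model, priors,
sampler, and design choices in full; `FORMATS.md` documents every file
format.

## Worked example

Simulate a balanced incomplete rating design — 500 ratees, 10 items over
5 attributes, 10 raters, each ratee judged by 3 raters — at the built-in
benchmark truth, then refit the facets-CDM:

```python
import numpy as np
import ratercdm as rc
from ratercdm import constants

qmatrix = constants.STUDY_QMATRIX
items = constants.study_item_params()
raters = [rc.RaterParams(severity_eta=e) for e in constants.STUDY_RATER_SEVERITIES]

config = rc.SimulationConfig(qmatrix, items, raters, "facets",
                             design="balanced", seed=7)
table = rc.simulate_facets(config)
print(f"{len(table)} ratings from {table.n_ratees} ratees x {table.n_items} items")

model = rc.FacetsCDM(qmatrix, n_iterations=2000, burn_in=1000, thin=10,
                     random_state=0).fit(table)
print("estimated severities:",
      np.round([r.severity_eta for r in model.rater_params_], 2))
print("generating severities:", constants.STUDY_RATER_SEVERITIES)
print(f"profile recovery: "
      f"{rc.profile_recovery_rate(model.predict(), table.true_profiles):.1f}%")
```

Output:

```
15000 ratings from 500 ratees x 10 items
estimated severities: [ 0.49  0.69  0.69  1.81 -0.46 -0.42 -0.15 -1.12  0.54 -2.07]
generating severities: [ 0.57  0.59  0.7   1.83 -0.5  -0.56 -0.1  -1.05  0.55 -2.03]
profile recovery: 79.8%
```

Reading the numbers: the ten rater severities (on the logit scale;
positive = severe) are recovered to within about ±0.1 from only three
raters per ratee, and 79.8% of the 500 ratees get their full 5-attribute
mastery pattern classified exactly right — noticeably below the ~98%
achievable when every rater judges every ratee, which is the central
trade-off these designs probe. `model.predict()` returns the classified
profiles, `model.predict_proba()` the per-attribute posterior mastery
probabilities, and `model.rhat_` the per-parameter convergence
diagnostics.

The same estimators compose with scikit-learn tooling (`get_params`,
`set_params`, `clone`), and everything is reachable from the command
line:

```
ratercdm simulate --model facets --design balanced --seed 7 --out sim/
ratercdm fit --ratings sim/ratings.csv --qmatrix sim/qmatrix.csv --model facets --out fit/
ratercdm evaluate --ratings sim/ratings.csv --qmatrix sim/qmatrix.csv --model facets
ratercdm replicate --study 1 --scale reduced --seed 1
```

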