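# Methods

## The measurement problem

Cognitive diagnosis models (CDMs) classify each respondent into a binary
mastery profile α ∈ {0,1}^K over K attributes, using a Q-matrix that
declares which attributes each item requires. When the items are
constructed responses marked by human raters, the observed score confounds
the ratee's profile with the rater's behaviour: a severe rater depresses
scores, an erratic one adds noise. This package implements two ways of
modelling that confound inside the log-linear cognitive diagnosis model
(LCDM), together with the simulation and evaluation machinery needed to
study how well the resulting profiles can be recovered.

## Models

**LCDM kernel.** The probability that a ratee with profile α succeeds on
item j is logistic in

&nbsp;&nbsp;λ_{j0} + Σ_k λ_{jk} α_k q_{jk} + Σ_{k<v} λ_{jkv} α_k α_v q_{jk} q_{jv} + …,

with main effects constrained positive so that mastery never lowers the
success probability. The DINA model is the constrained case keeping only
the intercept and the single top-order interaction over all required
attributes: each item then has a guessing probability g_j = σ(λ_{j0}) and
a slip probability s_j = 1 − σ(kernel at full mastery).

**Facets-CDM.** Raters enter as an additive severity η_r in the logit,
logit P(X_{ijr}=1) = λ_{j0} − η_r + kernel(α_i). Each rater's scores are
direct, independent measurements of the ratee, so more raters always add
information. Severities are identified only up to a location shift against
the intercepts; the pool mean is pinned at zero.

**HRM-CDM.** Raters are noisy readouts of a latent *ideal* binary category
ξ_{ij}, itself governed by the LCDM: P(ξ_{ij}=1|α_i) has the kernel above,
and the rating stage is a discretized normal signal-detection kernel,
P(k|ξ) ∝ exp(−(k − (ξ − φ_r))² / 2ψ_r²) normalized over k ∈ {0,1}. φ_r is
the rater's severity (positive = under-scores), ψ_r the rating
variability. With one shared ξ per (ratee, item), raters are conditionally
independent given ξ but marginally correlated, and extra raters can only
sharpen the reconstruction of ξ — they add no information about α beyond
it. The package also supports an independent-realization structure
(`xi_structure="per_rater"` in fitting, `shared_xi=False` in simulation)
in which every rater judges an independently realized category; the
likelihood then factorizes over single observations and additional raters
keep adding profile information.

**Standard-CDM comparators.** To quantify the cost of ignoring raters, a
rater-free LCDM can be fitted two ways: *virtual items* (each rater's
column of scores treated as another copy of the item with identical
parameters) and *virtual examinees* (each (ratee, rater) pair fitted as a
separate examinee, with attribute posteriors averaged across a ratee's
copies before classification).

## Estimation

A bespoke Metropolis-within-Gibbs sampler (the transition kernel is an
implementation choice; a self-contained sampler makes the exact-oracle
tests below possible). Each sweep updates:

1. **Profile-population parameters.** By default the latent profiles are
   modelled as independent Bernoulli attributes, α_k ~ Bern(p_k) with
   p_k ~ Beta(1,1), updated conjugately from the current profile
   assignments. A saturated alternative (Dirichlet over all 2^K class
   weights) is available via `PriorSpec(profile_prior="saturated")`. The
   independent form is the default because the saturated form's 2^K − 1
   free weights can support higher-likelihood but attribute-misaligned
   modes when the per-ratee information is weak: the extra weight
   parameters can re-describe misfit (such as rating-stage attenuation)
   as an unusual profile population, detaching the fitted "attributes"
   from the generating ones. With strong data the two priors give
   indistinguishable results.
2. **Ratee classes.** Categorical full conditional over the 2^K classes,
   computed in log space from matmul-accumulated sufficient statistics;
   for the shared-ξ HRM the ideal category is collapsed analytically
   (a two-term mixture per ratee-item). An explicitly ξ-augmented chain is
   retained solely to cross-check the collapsed conditional.
3. **Item weights.** Scalar random-walk Metropolis per weight against
   N(0, 4²) priors, positivity of main effects enforced by proposal
   rejection (equivalent to a truncated-normal prior).
4. **Rater parameters.** Facets: Metropolis on each η_r with a N(0,1)
   prior, followed by the identification transform η ← η − m,
   λ_{j0} ← λ_{j0} − m (m = mean η). Recentring *with* the compensating
   intercept shift leaves every linear predictor unchanged, so the
   constraint costs nothing in likelihood; recentring η alone would
   silently alter the model. HRM: Metropolis on φ_r (N(0,1) prior) and on
   log ψ_r (N(0, 4²) prior, so ψ is log-normal and always positive).
   When the posterior ψ_r falls below 0.2 the matching φ_r is weakly
   identified (its posterior is nearly flat); the sampler logs a warning.

Proposal step sizes adapt toward a 0.35 acceptance rate during burn-in
only, preserving detailed balance afterwards. Chains are seeded through
`numpy.random.SeedSequence` spawning, so a (seed, schedule) pair
reproduces retained draws exactly.

Default schedule: 2 chains × 10,000 iterations, 5,000 burn-in, keep every
10th draw. Convergence is monitored by the Gelman–Rubin potential scale
reduction factor per structural parameter; values below 1.1 are treated as
converged. Point estimates are expected-a-posteriori (EAP) means of the
retained draws; per-ratee class and mastery probabilities are
Rao-Blackwellized (the categorical full conditional is averaged over
retained sweeps rather than counting sampled labels).

Initialization: intercepts at the logit of the observed item mean (clipped
to [0.05, 0.95]), main effects at 1, interactions at 0.5, severities at 0,
ψ at 1, classes uniform. If the initial likelihood is non-finite the
sampler re-initializes up to five times and then fails loudly. Probability
clipping at 1e−12 guards the log-space accumulations; expected-score
clipping for the predictive discrepancy uses 1e−6.

## Synthetic data

**Profiles.** Abilities θ_i ~ MVN(0, Σ) with unit variances and a common
inter-attribute correlation ρ (default 0.5, a moderate value typical of
educational attributes); attribute k is mastered iff θ_ik ≥ Φ⁻¹(k/(K+1)),
with mastery granted on ties (a measure-zero rule fixed for
reproducibility). Mastery rates therefore fall from 1 − 1/(K+1) for the
first attribute to 1/(K+1) for the last.

**Designs.** Complete (fully crossed); balanced incomplete (10 rotating
three-rater blocks; at the benchmark size of 500 ratees and 10 raters each
rater judges exactly 150 ratees); unbalanced incomplete (same rotation
with block sizes 50, 68, 44, 58, 35, 51, 50, 55, 40, 49, giving rater
totals 139, 167, 162, 170, 137, 144, 136, 156, 145, 144); random (20
fully-crossed anchor ratees, every other ratee judged by 3 raters drawn
uniformly without replacement). Other (N, R) sizes reuse the rotating
block scheme with near-equal (balanced) or deterministically jittered
(unbalanced) block sizes. All four kinds are verified connected — raters
must be linked through shared ratees for severities to be comparable.

**Benchmark condition.** 500 ratees, 10 items over 5 attributes (five
single-attribute items, five two-attribute items), 10 raters. The
generating item weights imply guessing probabilities in [0.08, 0.20] and
slip probabilities in [0.07, 0.19]; two-attribute items carry their listed
main effect on *each* required attribute (the reading under which the slip
range comes out as printed). The generating severities span η ∈
[−2.03, 1.83] and sum to zero.

**Checklist condition.** A synthetic essay-marking dataset shaped like a
realistic application: 287 ratees × 52 binary checklist criteria over six
writing attributes (content, organization, grammar, vocabulary, academic
conventions, mechanics), 9 raters with 1–2 readers per essay, scores
generated under a shared-ξ HRM-DINA with two notably severe raters
(φ = 0.40 and 0.24) and variabilities from 0.37 to 1.28. It exists to
exercise the full empirical workflow (model comparison, severity tables,
fair scores) on data whose truth is known; it is synthetic and labelled as
such.

What the generator does **not** emulate: rater drift over time or
intra-rater severity fluctuation, item-by-rater interactions
(per-item sensitivities), polytomous scores, missingness beyond the
design structure, and Q-matrix misspecification. Passing recovery tests
therefore show that the estimators work when the model family is correct
and raters behave stationarily — not that real essay ratings satisfy
those assumptions.

## Evaluation

**Recovery.** For each structural parameter, bias = mean(EAP − truth) and
RMSE = √mean((EAP − truth)²) across replications. Profile recovery is
reported three ways: the **exact-match rate** (percentage of ratees whose
attribute-wise EAP ≥ 0.5 classification reproduces the full generating
pattern — the primary metric; ties at exactly 0.5 classify as mastered),
the attribute-wise rate, and the **posterior recovery rate** (mean
posterior probability assigned to the true pattern, i.e. the expected
fraction of posterior draws that reproduce it). The two pattern-level
metrics answer different questions — "is the point classification right?"
versus "how much posterior mass sits on the truth?" — and can differ by
10+ points on weakly informative designs, so both are reported.

**Study 1 (facets).** Data generated under the facets-CDM at the
benchmark truth for each rating design; each replication is refitted with
the facets-CDM and with the virtual-items standard CDM on the same data.
The headline contrasts: recovery degrades sharply from the complete to the
incomplete designs, and the facets model beats the rater-free fit wherever
the design leaves severities unbalanced across ratees.

**Study 2 (HRM).** Fully crossed design with three or six raters, unbiased
rating stage (φ = 0, ψ = 0.5) both in generation and (clamped) in fitting.
Each rater judges an independently realized ideal category. This is a
deliberate design choice: with one shared category per response, the
information about α saturates once ξ is pinned down — adding raters past
that point cannot raise recovery above the ceiling set by a single
error-free reading of each response — so a rater-count comparison
generated under shared categories cannot show the more-raters-help
effect the study is about. The *fitted*
HRM keeps its defining shared-category structure; the standard-CDM
comparator uses virtual examinees with attribute-level posterior
averaging (attribute-level rather than class-level averaging, the two
disagree after thresholding; class-level was measured and classifies
worse here).

**Fit statistics.** Posterior predictive p-value of a Bayesian chi-square
discrepancy: per retained draw, Σ (O − E)²/(E(1−E)) over observed cells
with E the model's score-1 probability at that draw (HRM: marginal over
ξ), compared against the same statistic on a dataset replicated from the
draw; the ppp is the fraction of draws where the replicate is at least as
discrepant. AIC/BIC use a plug-in construction: the observed-data
log-likelihood at the EAP estimates, marginalizing each ratee's class over
the estimated profile-population model, penalized by the count of free
structural parameters (item weights, estimated rater parameters with one
severity lost to the zero-mean constraint, plus K mastery rates or
2^K − 1 class weights) and n = number of observed scores. These are
plug-in Bayesian analogues, not maximum-likelihood criteria; they are
used for relative comparison between models on the same data.

**Fair scores.** The expected total score Σ_j P(success on j | α̂) under
the rater-free kernel — what the ratee would be expected to score with
rater effects purged. Contrasting fair with observed totals shows how
severe or lenient raters re-rank ratees.

## Shipped problem sizes

The `replicate` harness and the acceptance script run the studies at a
desk scale chosen to keep a full reproduction in the minutes range on one
CPU: 5 replications per condition with 2-chain, 2,000-iteration chains
(1,000 burn-in, thin 10). The full-scale configuration (100 replications,
10,000-iteration chains) is available via `--scale full`. At the reduced
scale the per-parameter RMSEs carry visible replication noise; the
recovery means are stable to a couple of percentage points.

## Known limitations

- The facets and HRM severities are not comparable across models (additive
  logit shift versus rating-stage displacement).
- The virtual-examinee standard comparator is doubly misspecified on HRM
  data (it ignores both the rating noise and the dependence between a
  ratee's copies); its fitted item parameters converge to a
  rating-stage-attenuated curve that is not exactly logistic, and its
  recovery is accordingly sensitive to where the sampler settles in that
  flat likelihood.
- Identification of φ_r degrades as ψ_r → 0 (flagged at ψ < 0.2).
- Polytomous scores, additional facets (e.g. criteria), random intra-rater
  effects, and covariate-explanatory extensions are out of scope; the
  model-spec surface leaves room for them but no implementation is
  provided.
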