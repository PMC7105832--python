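"""Metropolis-within-Gibbs estimation of CDMs with rater effects.

The sampler alternates four blocks:

1. the profile-population model — conjugate Beta draws of the K attribute
   mastery rates (independent-attribute prior, the default) or a conjugate
   Dirichlet draw of the 2^K class weights (saturated prior);
2. ratee classes z_i — categorical full conditional ∝ π_c × likelihood,
   computed in log space and, for the HRM, collapsed analytically over the
   latent ideal categories ξ;
3. item parameters — scalar random-walk Metropolis per weight, with the
   positivity constraint on main effects enforced by rejection;
4. rater parameters — Metropolis on η (facets; recentred to mean zero with
   the compensating shift absorbed into the intercepts, which leaves the
   likelihood invariant) or on φ and log ψ (HRM).

Proposal step sizes adapt towards a target acceptance rate during burn-in
only, so the retained portion of each chain is a valid Markov chain.
Convergence is monitored with the Gelman–Rubin potential scale reduction
factor across chains; values below 1.1 are conventionally taken as
converged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.special import expit

from .lcdm import DINA, SATURATED, ItemParams, enumerate_profiles
from .qmatrix import QMatrix
from .raters import RaterParams, hrm_rating_table
from .simulate import RatingsTable

logger = logging.getLogger(__name__)

_PCLIP = 1e-12
_TARGET_ACCEPT = 0.35
_MAX_INIT_RETRIES = 5


@dataclass(frozen=True)
class PriorSpec:
    """Prior scales: weakly informative normals on the structural parameters.

    Item intercepts, main effects (truncated to be positive) and
    interactions get N(0, item_sd²); facets severities N(0, eta_sd²) with
    the pool mean pinned at zero; HRM severities N(0, phi_sd²) and
    log-variabilities N(0, log_psi_sd²).

    ``profile_prior`` sets the latent-profile population model used in
    estimation: ``"independent"`` (default) treats attributes as
    independent Bernoulli(p_k) with Beta(1,1) hyperpriors on the K mastery
    rates — the conventional, well-identified choice for CDM fitting —
    while ``"saturated"`` places a uniform Dirichlet over all 2^K class
    weights.  The saturated form is assumption-free but, with weak
    per-ratee information, its 2^K − 1 free weights can absorb misfit and
    drift the item parameters away from the attribute-aligned mode.
    """

    item_sd: float = 4.0
    eta_sd: float = 1.0
    phi_sd: float = 1.0
    log_psi_sd: float = 4.0
    profile_prior: str = "independent"

    def __post_init__(self) -> None:
        for name in ("item_sd", "eta_sd", "phi_sd", "log_psi_sd"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.profile_prior not in ("independent", "saturated"):
            raise ValueError(f"unknown profile prior {self.profile_prior!r}")


@dataclass(frozen=True)
class ChainSchedule:
    """MCMC run length: iterations per chain, burn-in, thinning, chain count."""

    n_chains: int = 2
    n_iterations: int = 10_000
    burn_in: int = 5_000
    thin: int = 10

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be ≥ 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


REDUCED_SCHEDULE = ChainSchedule(n_chains=2, n_iterations=2_000, burn_in=1_000, thin=10)


@dataclass(frozen=True)
class ModelSpec:
    """Which rater model wraps the CDM, and which CDM kernel is fitted.

    ``xi_structure`` applies to the HRM only: ``"shared"`` places one latent
    ideal category per (ratee, item), read by all of its raters;
    ``"per_rater"`` gives every rater an independently realized category
    (the likelihood then factorizes over observations).
    """

    rater_model: Literal["standard", "facets", "hrm"]
    cdm: Literal["saturated", "dina"] = "saturated"
    xi_structure: Literal["shared", "per_rater"] = "shared"

    def __post_init__(self) -> None:
        if self.rater_model not in ("standard", "facets", "hrm"):
            raise ValueError(f"unknown rater model {self.rater_model!r}")
        if self.cdm not in ("saturated", "dina"):
            raise ValueError(f"unknown CDM constraint {self.cdm!r}")
        if self.xi_structure not in ("shared", "per_rater"):
            raise ValueError(f"unknown xi structure {self.xi_structure!r}")


# ---------------------------------------------------------------------------
# Internal data and item-structure preparation


@dataclass
class _Data:
    n_ratees: int
    n_items: int
    n_raters: int
    ratee: np.ndarray
    item: np.ndarray
    rater: np.ndarray
    score: np.ndarray

    @classmethod
    def from_table(cls, table: RatingsTable) -> "_Data":
        rec = table.records
        return cls(table.n_ratees, table.n_items, table.n_raters,
                   rec["ratee"].to_numpy(np.int64), rec["item"].to_numpy(np.int64),
                   rec["rater"].to_numpy(np.int64), rec["score"].to_numpy(np.int8))

    @property
    def n_obs(self) -> int:
        return self.ratee.size


def _all_subsets(required: tuple[int, ...]):
    from itertools import combinations
    for size in range(2, len(required) + 1):
        yield from combinations(required, size)


@dataclass
class _ItemStructure:
    """One item's kernel as a linear form over class-space columns."""

    design: np.ndarray          # (n_classes, p) columns: 1, α_k, Πα
    positive: np.ndarray        # (p,) bool — truncated-to-positive entries
    names: list[str]
    keys: list[tuple]           # ("intercept",) / ("main", k) / ("inter", subset)


def _build_item_structures(qmatrix: QMatrix, cdm: str,
                           profiles: np.ndarray) -> list[_ItemStructure]:
    structures = []
    for j in range(qmatrix.n_items):
        required = qmatrix.required(j)
        cols = [np.ones(profiles.shape[0])]
        positive = [False]
        names = [f"lambda[{j + 1},0]"]
        keys: list[tuple] = [("intercept",)]
        if cdm == "dina" and len(required) > 1:
            cols.append(profiles[:, required].prod(axis=1).astype(float))
            positive.append(True)
            names.append(f"lambda[{j + 1},top]")
            keys.append(("inter", tuple(required)))
        else:
            for k in required:
                cols.append(profiles[:, k].astype(float))
                positive.append(True)
                names.append(f"lambda[{j + 1},1,A{k + 1}]")
                keys.append(("main", k))
            if cdm == "saturated":
                for subset in _all_subsets(required):
                    cols.append(profiles[:, subset].prod(axis=1).astype(float))
                    positive.append(False)
                    names.append(
                        f"lambda[{j + 1},{len(subset)},"
                        + "x".join(f"A{k + 1}" for k in subset) + "]")
                    keys.append(("inter", subset))
        structures.append(_ItemStructure(np.column_stack(cols), np.array(positive),
                                         names, keys))
    return structures


def _beta_from_item_params(structure: _ItemStructure, params: ItemParams) -> np.ndarray:
    beta = np.zeros(structure.design.shape[1])
    for p, key in enumerate(structure.keys):
        if key[0] == "intercept":
            beta[p] = params.intercept
        elif key[0] == "main":
            beta[p] = params.main_effects.get(key[1], 0.0)
        else:
            subset = key[1]
            if len(subset) == 1:
                beta[p] = params.main_effects.get(subset[0], 0.0)
            else:
                beta[p] = params.interactions.get(tuple(subset), 0.0)
    return beta


def _item_params_from_beta(structure: _ItemStructure, beta: np.ndarray,
                           cdm: str) -> ItemParams:
    intercept = 0.0
    mains: dict[int, float] = {}
    inters: dict[tuple[int, ...], float] = {}
    for value, key in zip(beta, structure.keys):
        if key[0] == "intercept":
            intercept = float(value)
        elif key[0] == "main":
            mains[key[1]] = float(value)
        else:
            inters[tuple(key[1])] = float(value)
    tag = DINA if cdm == "dina" else SATURATED
    return ItemParams(intercept, mains, inters, tag)


# ---------------------------------------------------------------------------
# Posterior summary


@dataclass
class PosteriorSummary:
    """Retained draws and summaries of one model fit.

    ``draws`` stacks the structural parameters (item weights then rater
    parameters) as (n_chains, n_retained, P); ``class_weight_draws`` and
    ``class_assignment_draws`` carry π and the per-ratee class labels at the
    same retained iterations.  ``class_probs`` and ``mastery_probs`` are
    Rao-Blackwellized posterior means of the class membership and of
    attribute mastery.
    """

    spec: ModelSpec
    param_names: list[str]
    draws: np.ndarray
    class_weight_draws: np.ndarray
    class_assignment_draws: np.ndarray
    class_probs: np.ndarray
    mastery_probs: np.ndarray
    profiles: np.ndarray
    item_slices: list[slice]
    item_structures: list[_ItemStructure] = field(repr=False, default_factory=list)
    acceptance: dict = field(default_factory=dict)
    seed: int | None = None
    n_free_params: int = 0

    @property
    def n_params(self) -> int:
        return self.draws.shape[2]

    @property
    def flat_draws(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[2])

    @property
    def eap(self) -> np.ndarray:
        return self.flat_draws.mean(axis=0)

    @property
    def posterior_sd(self) -> np.ndarray:
        return self.flat_draws.std(axis=0, ddof=1)

    @property
    def rhat(self) -> np.ndarray:
        return gelman_rubin(self.draws)

    def eap_dict(self) -> dict[str, float]:
        return dict(zip(self.param_names, self.eap))

    def eap_item_params(self, cdm: str | None = None) -> list[ItemParams]:
        cdm = cdm or self.spec.cdm
        eap = self.eap
        return [_item_params_from_beta(s, eap[sl], cdm)
                for s, sl in zip(self.item_structures, self.item_slices)]

    def eap_rater_params(self) -> list[RaterParams]:
        eap = self.eap_dict()
        out = []
        r = 1
        while f"eta[{r}]" in eap or f"phi[{r}]" in eap:
            if self.spec.rater_model == "facets":
                out.append(RaterParams(severity_eta=eap[f"eta[{r}]"]))
            else:
                out.append(RaterParams(severity_phi=eap.get(f"phi[{r}]", 0.0),
                                       variability_psi=eap.get(f"psi[{r}]", 1.0)))
            r += 1
        return out

    def eap_class_weights(self) -> np.ndarray:
        return self.class_weight_draws.reshape(-1, self.class_weight_draws.shape[2]).mean(axis=0)


def gelman_rubin(draws: np.ndarray) -> np.ndarray:
    """Potential scale reduction factor per parameter.

    ``draws`` has shape (n_chains, n_retained, P) with equal retained
    lengths.  Parameters that are constant across all chains get R-hat 1.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 2:
        draws = draws[:, :, None]
    m, n, _ = draws.shape
    if m < 2:
        raise ValueError("Gelman–Rubin diagnostic needs ≥2 chains")
    if n < 2:
        raise ValueError("Gelman–Rubin diagnostic needs ≥2 retained draws per chain")
    chain_means = draws.mean(axis=1)
    chain_vars = draws.var(axis=1, ddof=1)
    W = chain_vars.mean(axis=0)
    B = n * chain_means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / W)
    rhat[(W == 0) & (B == 0)] = 1.0
    return rhat


def classify_profiles(mastery_probs: np.ndarray) -> np.ndarray:
    """Attribute-wise MAP classification: mastery iff posterior probability ≥ 0.5.

    A probability of exactly 0.5 classifies as mastered (documented tie rule).
    """
    return (np.asarray(mastery_probs) >= 0.5).astype(np.int8)


# ---------------------------------------------------------------------------
# Adaptive scalar Metropolis helper


class _Scalar:
    """One random-walk-updated scalar with burn-in-only step adaptation."""

    __slots__ = ("step", "accepts", "proposals")

    def __init__(self, _value: float, step: float):
        self.step = step
        self.accepts = 0
        self.proposals = 0

    def adapt(self, accepted: bool, iteration: int) -> None:
        gain = min(0.25, 5.0 / (iteration + 10.0))
        self.step *= float(np.exp(gain * ((1.0 if accepted else 0.0) - _TARGET_ACCEPT)))
        self.step = float(np.clip(self.step, 1e-3, 10.0))


# ---------------------------------------------------------------------------
# Likelihood kernels (shared with the evaluation module)


def class_loglik_facets(data: _Data, kernels: np.ndarray, eta: np.ndarray,
                        d_obs: np.ndarray, d_one: np.ndarray) -> np.ndarray:
    """(N, C) log-likelihood of each ratee under each latent class (facets family)."""
    J, C = kernels.shape
    R = eta.size
    prob = expit(kernels[:, None, :] - eta[None, :, None])  # (J, R, C)
    prob = np.clip(prob, _PCLIP, 1.0 - _PCLIP)
    lp1 = np.log(prob).reshape(J * R, C)
    lp0 = np.log1p(-prob).reshape(J * R, C)
    return d_obs @ lp0 + d_one @ (lp1 - lp0)


def class_loglik_hrm(kernels: np.ndarray, log_a: np.ndarray) -> np.ndarray:
    """(N, C) collapsed log-likelihood under the HRM.

    ``log_a[i, j, ξ]`` is the log-probability of ratee i's observed scores on
    item j given latent category ξ; the ξ mixture is summed analytically.
    """
    p1 = np.clip(expit(kernels), _PCLIP, 1.0 - _PCLIP)  # (J, C)
    m = log_a.max(axis=2)  # (N, J)
    a0 = np.exp(log_a[:, :, 0] - m)
    a1 = np.exp(log_a[:, :, 1] - m)
    mix = a1[:, :, None] * p1[None] + a0[:, :, None] * (1.0 - p1[None])
    return m.sum(axis=1)[:, None] + np.log(mix).sum(axis=1)


def class_loglik_hrm_per_rater(data: _Data, kernels: np.ndarray, table: np.ndarray,
                               d_obs: np.ndarray, d_one: np.ndarray) -> np.ndarray:
    """(N, C) log-likelihood when every rater reads an independent ξ realization.

    The observation-level marginal P(k=1 | c, r) = p1(j,c)·P(k=1|ξ=1,r)
    + (1−p1(j,c))·P(k=1|ξ=0,r) factorizes over cells, so the facets-style
    matmul accumulation applies with attenuated probabilities.
    """
    p1 = expit(kernels)  # (J, C)
    t11 = table[:, 1, 1]
    t01 = table[:, 0, 1]
    prob = p1[:, None, :] * t11[None, :, None] + (1 - p1[:, None, :]) * t01[None, :, None]
    prob = np.clip(prob, _PCLIP, 1.0 - _PCLIP)
    J, R, C = prob.shape
    lp1 = np.log(prob).reshape(J * R, C)
    lp0 = np.log1p(-prob).reshape(J * R, C)
    return d_obs @ lp0 + d_one @ (lp1 - lp0)


def hrm_log_a(data: _Data, table: np.ndarray) -> np.ndarray:
    """Accumulate log P(observed scores | ξ) per (ratee, item, ξ) from the rating table."""
    log_t = np.log(np.clip(table, _PCLIP, 1.0))  # (R, xi, k)
    log_a = np.zeros((data.n_ratees, data.n_items, 2))
    contrib = log_t[data.rater, :, data.score]  # (M, 2)
    np.add.at(log_a, (data.ratee, data.item), contrib)
    return log_a


# ---------------------------------------------------------------------------
# The samplers


class _BaseSampler:
    def __init__(self, spec: ModelSpec, data: _Data, qmatrix: QMatrix,
                 priors: PriorSpec, rng: np.random.Generator, *,
                 fix_item_params: Sequence[ItemParams] | None = None,
                 fix_rater_params: Sequence[RaterParams] | None = None,
                 fix_class_weights: np.ndarray | None = None,
                 init_item_params: Sequence[ItemParams] | None = None,
                 likelihood_scale: float = 1.0):
        self.spec = spec
        self.data = data
        self.qmatrix = qmatrix
        self.priors = priors
        self.rng = rng
        self.likelihood_scale = float(likelihood_scale)
        self.profiles = enumerate_profiles(qmatrix.n_attributes)
        self.n_classes = self.profiles.shape[0]
        self.structures = _build_item_structures(qmatrix, spec.cdm, self.profiles)
        self.fix_items = fix_item_params is not None
        self.fix_raters = fix_rater_params is not None
        self.fix_weights = fix_class_weights is not None
        self._fixed_weights = (np.asarray(fix_class_weights, dtype=float)
                               if self.fix_weights else None)

        if spec.rater_model in ("facets", "hrm"):
            present = np.unique(data.rater)
            missing = sorted(set(range(data.n_raters)) - set(present.tolist()))
            if missing:
                raise ValueError(
                    f"rater(s) {[r + 1 for r in missing]} have no observations; "
                    f"their parameters are unidentifiable")

        # Item weights.
        source = fix_item_params or init_item_params
        if source is not None:
            self.beta = [_beta_from_item_params(s, p)
                         for s, p in zip(self.structures, source)]
        else:
            item_means = np.full(data.n_items, 0.5)
            sums = np.bincount(data.item, weights=data.score, minlength=data.n_items)
            counts = np.bincount(data.item, minlength=data.n_items)
            item_means[counts > 0] = np.clip(sums[counts > 0] / counts[counts > 0],
                                             0.05, 0.95)
            self.beta = []
            for j, s in enumerate(self.structures):
                b = np.zeros(s.design.shape[1])
                b[0] = np.log(item_means[j] / (1 - item_means[j]))
                b[s.positive] = 1.0
                for p, key in enumerate(s.keys):
                    if key[0] == "inter" and not s.positive[p]:
                        b[p] = 0.5
                self.beta.append(b)
        self.item_steps = [[_Scalar(0.0, 0.2) for _ in range(b.size)] for b in self.beta]
        self._init_raters(fix_rater_params)

        self.log_pi = np.full(self.n_classes, -np.log(self.n_classes))
        if self.fix_weights:
            self.log_pi = np.log(np.clip(self._fixed_weights, _PCLIP, 1.0))
        self.z = rng.integers(self.n_classes, size=data.n_ratees)

    # --- hooks -------------------------------------------------------------
    def _init_raters(self, fixed) -> None:
        raise NotImplementedError

    def kernels(self) -> np.ndarray:
        out = np.empty((self.data.n_items, self.n_classes))
        for j, (s, b) in enumerate(zip(self.structures, self.beta)):
            out[j] = s.design @ b
        return out

    # --- shared steps ------------------------------------------------------
    def sweep(self, iteration: int, adapt: bool) -> None:
        self._update_class_weights()
        self._update_classes()
        if not self.fix_items:
            self._update_items(iteration, adapt)
        if not self.fix_raters:
            self._update_raters(iteration, adapt)

    def _update_class_weights(self) -> None:
        if self.fix_weights:
            return
        if self.priors.profile_prior == "independent":
            # α_k ~ Bernoulli(p_k), p_k ~ Beta(1, 1): conjugate update of the
            # K mastery rates from the current profile assignments.
            alpha_z = self.profiles[self.z]  # (N, K)
            m = alpha_z.sum(axis=0).astype(float)
            n = float(alpha_z.shape[0])
            p = self.rng.beta(1.0 + m, 1.0 + n - m)
            p = np.clip(p, _PCLIP, 1.0 - _PCLIP)
            self.log_pi = (self.profiles @ np.log(p)
                           + (1 - self.profiles) @ np.log1p(-p))
        else:
            counts = np.bincount(self.z, minlength=self.n_classes)
            pi = self.rng.dirichlet(1.0 + counts)
            self.log_pi = np.log(np.clip(pi, _PCLIP, 1.0))

    def _class_loglik(self) -> np.ndarray:
        raise NotImplementedError

    def _update_classes(self) -> None:
        logpost = self.likelihood_scale * self._class_loglik() + self.log_pi[None, :]
        logpost -= logpost.max(axis=1, keepdims=True)
        post = np.exp(logpost)
        post /= post.sum(axis=1, keepdims=True)
        self.class_post = post  # Rao-Blackwellized conditional, reused by summaries
        cum = post.cumsum(axis=1)
        u = self.rng.random(post.shape[0])[:, None]
        self.z = (u > cum).sum(axis=1)

    def current_class_weights(self) -> np.ndarray:
        return np.exp(self.log_pi)


class _FacetsSampler(_BaseSampler):
    """Standard CDM (η ≡ 0) and facets-CDM sampler.

    Sufficient statistics per sweep are the counts n1[j, r, c] (score-1
    observations) and n[j, r, c] (all observations) over current classes,
    which make the item and rater Metropolis steps O(R·C) and O(J·C).
    """

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        d = self.data
        self.pair = d.item * d.n_raters + d.rater
        n_pairs = d.n_items * d.n_raters
        self.d_obs = np.zeros((d.n_ratees, n_pairs))
        self.d_obs[d.ratee, self.pair] = 1.0
        self.d_one = np.zeros((d.n_ratees, n_pairs))
        self.d_one[d.ratee, self.pair] = d.score.astype(float)

    def _init_raters(self, fixed) -> None:
        if self.spec.rater_model == "standard":
            self.eta = np.zeros(self.data.n_raters)
            self.fix_raters = True
            return
        if fixed is not None:
            self.eta = np.array([r.severity_eta for r in fixed], dtype=float)
        else:
            self.eta = np.zeros(self.data.n_raters)
        self.eta_steps = [_Scalar(0.0, 0.1) for _ in range(self.data.n_raters)]

    def _class_loglik(self) -> np.ndarray:
        return class_loglik_facets(self.data, self.kernels(), self.eta,
                                   self.d_obs, self.d_one)

    def _counts(self) -> tuple[np.ndarray, np.ndarray]:
        d = self.data
        flat = self.pair * self.n_classes + self.z[d.ratee]
        size = d.n_items * d.n_raters * self.n_classes
        n1 = np.bincount(flat, weights=d.score, minlength=size)
        nt = np.bincount(flat, minlength=size)
        shape = (d.n_items, d.n_raters, self.n_classes)
        return n1.reshape(shape), nt.reshape(shape)

    def _item_prob(self, kern_row: np.ndarray) -> np.ndarray:
        """(R, C) success probabilities of one item, per rater and class."""
        return np.clip(expit(kern_row[None, :] - self.eta[:, None]),
                       _PCLIP, 1.0 - _PCLIP)

    def _block_loglik(self, kern_row: np.ndarray,
                      n1: np.ndarray, nt: np.ndarray) -> float:
        prob = self._item_prob(kern_row)
        return float((n1 * np.log(prob) + (nt - n1) * np.log1p(-prob)).sum())

    def _update_items(self, iteration: int, adapt: bool) -> None:
        n1, nt = self._counts()
        sd = self.priors.item_sd
        for j, (structure, beta) in enumerate(zip(self.structures, self.beta)):
            kern = structure.design @ beta
            cur_ll = self._block_loglik(kern, n1[j], nt[j])
            for p, scalar in enumerate(self.item_steps[j]):
                prop = beta[p] + scalar.step * self.rng.standard_normal()
                accepted = False
                if not (structure.positive[p] and prop <= 0.0):
                    new_kern = kern + structure.design[:, p] * (prop - beta[p])
                    new_ll = self._block_loglik(new_kern, n1[j], nt[j])
                    log_ratio = (self.likelihood_scale * (new_ll - cur_ll)
                                 + (beta[p] ** 2 - prop ** 2) / (2 * sd ** 2))
                    if np.log(self.rng.random()) < log_ratio:
                        beta[p] = prop
                        kern = new_kern
                        cur_ll = new_ll
                        accepted = True
                scalar.proposals += 1
                scalar.accepts += int(accepted)
                if adapt:
                    scalar.adapt(accepted, iteration)

    def _update_raters(self, iteration: int, adapt: bool) -> None:
        n1, nt = self._counts()
        kernels = self.kernels()
        sd = self.priors.eta_sd
        for r, scalar in enumerate(self.eta_steps):
            prob = np.clip(expit(kernels - self.eta[r]), _PCLIP, 1.0 - _PCLIP)
            cur_ll = float((n1[:, r] * np.log(prob)
                            + (nt[:, r] - n1[:, r]) * np.log1p(-prob)).sum())
            prop = self.eta[r] + scalar.step * self.rng.standard_normal()
            prob_new = np.clip(expit(kernels - prop), _PCLIP, 1.0 - _PCLIP)
            new_ll = float((n1[:, r] * np.log(prob_new)
                            + (nt[:, r] - n1[:, r]) * np.log1p(-prob_new)).sum())
            log_ratio = (self.likelihood_scale * (new_ll - cur_ll)
                         + (self.eta[r] ** 2 - prop ** 2) / (2 * sd ** 2))
            accepted = np.log(self.rng.random()) < log_ratio
            if accepted:
                self.eta[r] = prop
            scalar.proposals += 1
            scalar.accepts += int(accepted)
            if adapt:
                scalar.adapt(bool(accepted), iteration)
        # Identification: recentre η and absorb the shift into the intercepts,
        # which leaves every linear predictor λ_j0 − η_r unchanged.
        shift = self.eta.mean()
        if shift != 0.0:
            self.eta -= shift
            for beta in self.beta:
                beta[0] -= shift

    def rater_names(self) -> list[str]:
        if self.spec.rater_model == "standard":
            return []
        return [f"eta[{r + 1}]" for r in range(self.data.n_raters)]

    def rater_draw(self) -> np.ndarray:
        if self.spec.rater_model == "standard":
            return np.empty(0)
        return self.eta.copy()


class _HRMPerRaterSampler(_FacetsSampler):
    """HRM sampler for independently realized ideal categories (ξ_ijr).

    With one ξ per observation the collapsed likelihood factorizes over
    cells, so the facets sufficient-statistic machinery applies with the
    success probability attenuated through each rater's rating stage.
    """

    def _init_raters(self, fixed) -> None:
        self.eta = np.zeros(self.data.n_raters)  # unused; keeps base hooks valid
        if fixed is not None:
            self.phi = np.array([r.severity_phi for r in fixed], dtype=float)
            self.log_psi = np.log([r.variability_psi for r in fixed])
        else:
            self.phi = np.zeros(self.data.n_raters)
            self.log_psi = np.zeros(self.data.n_raters)
        self.phi_steps = [_Scalar(0.0, 0.2) for _ in range(self.data.n_raters)]
        self.psi_steps = [_Scalar(0.0, 0.2) for _ in range(self.data.n_raters)]
        self._refresh_table()

    def _refresh_table(self) -> None:
        self.table = hrm_rating_table(
            [RaterParams(severity_phi=p, variability_psi=float(np.exp(lp)))
             for p, lp in zip(self.phi, self.log_psi)])

    def _class_loglik(self) -> np.ndarray:
        return class_loglik_hrm_per_rater(self.data, self.kernels(), self.table,
                                          self.d_obs, self.d_one)

    def _item_prob(self, kern_row: np.ndarray) -> np.ndarray:
        p1 = expit(kern_row)  # (C,)
        t11 = self.table[:, 1, 1][:, None]
        t01 = self.table[:, 0, 1][:, None]
        return np.clip(t11 * p1[None, :] + t01 * (1.0 - p1[None, :]),
                       _PCLIP, 1.0 - _PCLIP)

    def _update_raters(self, iteration: int, adapt: bool) -> None:
        n1, nt = self._counts()
        p1 = expit(self.kernels())  # (J, C)

        def rater_ll(r: int, table_r: np.ndarray) -> float:
            prob = np.clip(p1 * table_r[1, 1] + (1.0 - p1) * table_r[0, 1],
                           _PCLIP, 1.0 - _PCLIP)
            return float((n1[:, r] * np.log(prob)
                          + (nt[:, r] - n1[:, r]) * np.log1p(-prob)).sum())

        for r in range(self.data.n_raters):
            for which, scalar in (("phi", self.phi_steps[r]), ("psi", self.psi_steps[r])):
                phi_new, log_psi_new = self.phi[r], self.log_psi[r]
                if which == "phi":
                    phi_new = phi_new + scalar.step * self.rng.standard_normal()
                    log_prior_delta = ((self.phi[r] ** 2 - phi_new ** 2)
                                       / (2 * self.priors.phi_sd ** 2))
                else:
                    log_psi_new = log_psi_new + scalar.step * self.rng.standard_normal()
                    log_prior_delta = ((self.log_psi[r] ** 2 - log_psi_new ** 2)
                                       / (2 * self.priors.log_psi_sd ** 2))
                new_table = hrm_rating_table(
                    [RaterParams(severity_phi=phi_new,
                                 variability_psi=float(np.exp(log_psi_new)))])[0]
                log_ratio = (self.likelihood_scale
                             * (rater_ll(r, new_table) - rater_ll(r, self.table[r]))
                             + log_prior_delta)
                accepted = np.log(self.rng.random()) < log_ratio
                if accepted:
                    self.phi[r], self.log_psi[r] = phi_new, log_psi_new
                    self.table[r] = new_table
                scalar.proposals += 1
                scalar.accepts += int(accepted)
                if adapt:
                    scalar.adapt(bool(accepted), iteration)

    def rater_names(self) -> list[str]:
        names = [f"phi[{r + 1}]" for r in range(self.data.n_raters)]
        names += [f"psi[{r + 1}]" for r in range(self.data.n_raters)]
        return names

    def rater_draw(self) -> np.ndarray:
        return np.concatenate([self.phi, np.exp(self.log_psi)])


class _HRMSampler(_BaseSampler):
    """HRM-CDM sampler with the latent ideal category collapsed analytically.

    The per-(ratee, item) likelihood given a class c is
    ``p1(j,c)·A1 + (1−p1(j,c))·A0`` where A_ξ multiplies the rating-stage
    probabilities of the observed scores across the item's raters.  An
    explicitly ξ-augmented mode is kept for cross-checking the collapsed
    conditional.
    """

    def __init__(self, *args, augmented: bool = False, **kwargs):
        self.augmented = augmented
        super().__init__(*args, **kwargs)
        d = self.data
        self.obs_by_rater = [np.flatnonzero(d.rater == r) for r in range(d.n_raters)]
        self._refresh_log_a()
        if augmented:
            self.xi = (self.rng.random((d.n_ratees, d.n_items)) < 0.5).astype(np.int8)

    def _init_raters(self, fixed) -> None:
        if fixed is not None:
            self.phi = np.array([r.severity_phi for r in fixed], dtype=float)
            self.log_psi = np.log([r.variability_psi for r in fixed])
        else:
            self.phi = np.zeros(self.data.n_raters)
            self.log_psi = np.zeros(self.data.n_raters)
        self.phi_steps = [_Scalar(0.0, 0.2) for _ in range(self.data.n_raters)]
        self.psi_steps = [_Scalar(0.0, 0.2) for _ in range(self.data.n_raters)]

    def _rater_params(self) -> list[RaterParams]:
        return [RaterParams(severity_phi=p, variability_psi=float(np.exp(lp)))
                for p, lp in zip(self.phi, self.log_psi)]

    def _refresh_log_a(self) -> None:
        self.table = hrm_rating_table(self._rater_params())
        self.log_a = hrm_log_a(self.data, self.table)

    def _class_loglik(self) -> np.ndarray:
        if self.augmented:
            p1 = np.clip(expit(self.kernels()), _PCLIP, 1.0 - _PCLIP)  # (J, C)
            return self.xi @ np.log(p1) + (1 - self.xi) @ np.log1p(-p1)
        return class_loglik_hrm(self.kernels(), self.log_a)

    def _update_classes(self) -> None:
        super()._update_classes()
        if self.augmented:
            # ξ_ij | z, data ~ Bernoulli ∝ p1·A1 vs (1−p1)·A0
            p1 = np.clip(expit(self.kernels()), _PCLIP, 1.0 - _PCLIP)[:, self.z].T
            m = self.log_a.max(axis=2)
            w1 = np.exp(self.log_a[:, :, 1] - m) * p1
            w0 = np.exp(self.log_a[:, :, 0] - m) * (1.0 - p1)
            self.xi = (self.rng.random(w1.shape) < w1 / (w1 + w0)).astype(np.int8)

    def _mix_cache(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.log_a.max(axis=2)
        return np.exp(self.log_a[:, :, 0] - m), np.exp(self.log_a[:, :, 1] - m)

    def _update_items(self, iteration: int, adapt: bool) -> None:
        sd = self.priors.item_sd
        if self.augmented:
            xi_sum = np.zeros((self.data.n_items, self.n_classes))
            n_tot = np.zeros((self.data.n_items, self.n_classes))
            cls_one_hot = np.zeros((self.data.n_ratees, self.n_classes))
            cls_one_hot[np.arange(self.data.n_ratees), self.z] = 1.0
            xi_sum = self.xi.T @ cls_one_hot
            n_tot = np.ones_like(self.xi, dtype=float).T @ cls_one_hot
        else:
            a0, a1 = self._mix_cache()
        for j, (structure, beta) in enumerate(zip(self.structures, self.beta)):
            kern = structure.design @ beta

            def item_ll(kern_row: np.ndarray) -> float:
                p1 = np.clip(expit(kern_row), _PCLIP, 1.0 - _PCLIP)
                if self.augmented:
                    return float((xi_sum[j] * np.log(p1)
                                  + (n_tot[j] - xi_sum[j]) * np.log1p(-p1)).sum())
                pz = p1[self.z]
                return float(np.log(a1[:, j] * pz + a0[:, j] * (1.0 - pz)).sum())

            cur_ll = item_ll(kern)
            for p, scalar in enumerate(self.item_steps[j]):
                prop = beta[p] + scalar.step * self.rng.standard_normal()
                accepted = False
                if not (structure.positive[p] and prop <= 0.0):
                    new_kern = kern + structure.design[:, p] * (prop - beta[p])
                    new_ll = item_ll(new_kern)
                    log_ratio = (self.likelihood_scale * (new_ll - cur_ll)
                                 + (beta[p] ** 2 - prop ** 2) / (2 * sd ** 2))
                    if np.log(self.rng.random()) < log_ratio:
                        beta[p] = prop
                        kern = new_kern
                        cur_ll = new_ll
                        accepted = True
                scalar.proposals += 1
                scalar.accepts += int(accepted)
                if adapt:
                    scalar.adapt(accepted, iteration)

    def _pair_loglik(self, log_a_entries: np.ndarray,
                     p1z: np.ndarray) -> np.ndarray:
        m = log_a_entries.max(axis=1)
        return m + np.log(np.exp(log_a_entries[:, 1] - m) * p1z
                          + np.exp(log_a_entries[:, 0] - m) * (1.0 - p1z))

    def _update_raters(self, iteration: int, adapt: bool) -> None:
        kernels = self.kernels()
        p1_table = np.clip(expit(kernels), _PCLIP, 1.0 - _PCLIP)
        d = self.data
        for r in range(d.n_raters):
            idx = self.obs_by_rater[r]
            if idx.size == 0:
                continue
            i_r, j_r, k_r = d.ratee[idx], d.item[idx], d.score[idx]
            p1z = p1_table[j_r, self.z[i_r]]
            for which, scalar in (("phi", self.phi_steps[r]), ("psi", self.psi_steps[r])):
                phi_new, log_psi_new = self.phi[r], self.log_psi[r]
                if which == "phi":
                    phi_new = phi_new + scalar.step * self.rng.standard_normal()
                    log_prior_delta = (self.phi[r] ** 2 - phi_new ** 2) / (2 * self.priors.phi_sd ** 2)
                else:
                    log_psi_new = log_psi_new + scalar.step * self.rng.standard_normal()
                    log_prior_delta = ((self.log_psi[r] ** 2 - log_psi_new ** 2)
                                       / (2 * self.priors.log_psi_sd ** 2))
                new_table = hrm_rating_table(
                    [RaterParams(severity_phi=phi_new,
                                 variability_psi=float(np.exp(log_psi_new)))])[0]
                log_t_old = np.log(np.clip(self.table[r], _PCLIP, 1.0))
                log_t_new = np.log(np.clip(new_table, _PCLIP, 1.0))
                old_entries = self.log_a[i_r, j_r]  # (m, 2)
                new_entries = old_entries - log_t_old[:, k_r].T + log_t_new[:, k_r].T
                delta_ll = float((self._pair_loglik(new_entries, p1z)
                                  - self._pair_loglik(old_entries, p1z)).sum())
                log_ratio = self.likelihood_scale * delta_ll + log_prior_delta
                accepted = np.log(self.rng.random()) < log_ratio
                if accepted:
                    self.phi[r], self.log_psi[r] = phi_new, log_psi_new
                    self.table[r] = new_table
                    self.log_a[i_r, j_r] = new_entries
                scalar.proposals += 1
                scalar.accepts += int(accepted)
                if adapt:
                    scalar.adapt(bool(accepted), iteration)
        if np.exp(self.log_psi).min() < 0.2 and not getattr(self, "_psi_warned", False):
            self._psi_warned = True
            logger.warning(
                "posterior rater variability ψ < 0.2 for some rater; the matching "
                "severity φ is weakly identified (near-uniform posterior)")

    def rater_names(self) -> list[str]:
        names = [f"phi[{r + 1}]" for r in range(self.data.n_raters)]
        names += [f"psi[{r + 1}]" for r in range(self.data.n_raters)]
        return names

    def rater_draw(self) -> np.ndarray:
        return np.concatenate([self.phi, np.exp(self.log_psi)])


# ---------------------------------------------------------------------------
# The public fit entry point


def _make_sampler(spec: ModelSpec, data: _Data, qmatrix: QMatrix, priors: PriorSpec,
                  rng: np.random.Generator, **kwargs) -> _BaseSampler:
    if spec.rater_model in ("standard", "facets"):
        kwargs.pop("augmented", None)
        return _FacetsSampler(spec, data, qmatrix, priors, rng, **kwargs)
    if spec.xi_structure == "per_rater":
        kwargs.pop("augmented", None)
        return _HRMPerRaterSampler(spec, data, qmatrix, priors, rng, **kwargs)
    return _HRMSampler(spec, data, qmatrix, priors, rng, **kwargs)


def fit(spec: ModelSpec, table: RatingsTable, qmatrix: QMatrix,
        priors: PriorSpec | None = None, schedule: ChainSchedule | None = None,
        seed: int = 0, *, fix_item_params: Sequence[ItemParams] | None = None,
        fix_rater_params: Sequence[RaterParams] | None = None,
        fix_class_weights: np.ndarray | None = None,
        init_item_params: Sequence[ItemParams] | None = None,
        likelihood_scale: float = 1.0, augmented: bool = False,
        verbose: bool = False) -> PosteriorSummary:
    """Fit a CDM (standard / facets / HRM) by Metropolis-within-Gibbs.

    Runs ``schedule.n_chains`` independent chains from dispersed seeds,
    discards the burn-in, thins the remainder, and returns the retained
    draws with Rao-Blackwellized class and mastery probabilities.
    ``fix_*`` arguments clamp blocks of parameters at supplied values
    (used e.g. when the rating stage is known, or for exact-oracle tests);
    ``likelihood_scale=0`` disables the data likelihood so the chain
    targets the prior.
    """
    priors = priors or PriorSpec()
    schedule = schedule or ChainSchedule()
    data = _Data.from_table(table)
    if data.item.max() >= qmatrix.n_items:
        raise ValueError("ratings reference an item missing from the Q-matrix")

    seed_seq = np.random.SeedSequence(seed)
    chain_seeds = seed_seq.spawn(schedule.n_chains)

    all_draws, all_pi, all_z = [], [], []
    class_prob_accum = np.zeros((data.n_ratees, 2 ** qmatrix.n_attributes))
    param_names: list[str] = []
    item_slices: list[slice] = []
    acceptance: dict[str, float] = {}
    structures = None
    profiles = enumerate_profiles(qmatrix.n_attributes)

    for c_idx, child in enumerate(chain_seeds):
        rng = np.random.default_rng(child)
        sampler = None
        for attempt in range(_MAX_INIT_RETRIES):
            sampler = _make_sampler(
                spec, data, qmatrix, priors, rng,
                fix_item_params=fix_item_params, fix_rater_params=fix_rater_params,
                fix_class_weights=fix_class_weights,
                init_item_params=init_item_params,
                likelihood_scale=likelihood_scale, augmented=augmented)
            if np.isfinite(sampler._class_loglik()).all():
                break
            logger.warning("non-finite likelihood at initialization; retrying (%d)",
                           attempt + 1)
        else:
            raise RuntimeError(
                f"could not initialize a finite likelihood after {_MAX_INIT_RETRIES} tries")

        if not param_names:
            structures = sampler.structures
            pos = 0
            for s in structures:
                param_names.extend(s.names)
                item_slices.append(slice(pos, pos + len(s.names)))
                pos += len(s.names)
            param_names.extend(sampler.rater_names())

        chain_draws = np.empty((schedule.n_retained, len(param_names)))
        chain_pi = np.empty((schedule.n_retained, sampler.n_classes))
        chain_z = np.empty((schedule.n_retained, data.n_ratees), dtype=np.int32)
        kept = 0
        for t in range(schedule.n_iterations):
            sampler.sweep(t, adapt=t < schedule.burn_in)
            if t >= schedule.burn_in and (t - schedule.burn_in) % schedule.thin == 0 \
                    and kept < schedule.n_retained:
                flat = np.concatenate([b for b in sampler.beta] + [sampler.rater_draw()])
                chain_draws[kept] = flat
                chain_pi[kept] = sampler.current_class_weights()
                chain_z[kept] = sampler.z
                class_prob_accum += sampler.class_post
                kept += 1
            if verbose and (t + 1) % 500 == 0:
                logger.info("chain %d: iteration %d/%d", c_idx + 1, t + 1,
                            schedule.n_iterations)
        all_draws.append(chain_draws)
        all_pi.append(chain_pi)
        all_z.append(chain_z)
        for name, group in (("items", [s for row in sampler.item_steps for s in row]),):
            props = sum(s.proposals for s in group)
            if props:
                acceptance[name] = sum(s.accepts for s in group) / props
        if isinstance(sampler, _FacetsSampler) and spec.rater_model == "facets":
            props = sum(s.proposals for s in sampler.eta_steps)
            if props:
                acceptance["raters"] = sum(s.accepts for s in sampler.eta_steps) / props
        if isinstance(sampler, _HRMSampler) and not sampler.fix_raters:
            group = sampler.phi_steps + sampler.psi_steps
            props = sum(s.proposals for s in group)
            if props:
                acceptance["raters"] = sum(s.accepts for s in group) / props

    draws = np.stack(all_draws)
    class_probs = class_prob_accum / (schedule.n_chains * schedule.n_retained)
    mastery = class_probs @ profiles

    # Count free structural parameters (item + rater + class weights); the
    # facets zero-mean constraint removes one severity degree of freedom.
    n_item_names = sum(len(s.names) for s in (structures or []))
    n_free = 0 if fix_item_params is not None else n_item_names
    n_rater_names = len(param_names) - n_item_names
    if fix_rater_params is None and spec.rater_model == "facets":
        n_free += max(n_rater_names - 1, 0)
    elif fix_rater_params is None and spec.rater_model == "hrm":
        n_free += n_rater_names
    if fix_class_weights is None:
        n_free += (qmatrix.n_attributes if priors.profile_prior == "independent"
                   else 2 ** qmatrix.n_attributes - 1)

    return PosteriorSummary(
        spec=spec, param_names=param_names, draws=draws,
        class_weight_draws=np.stack(all_pi), class_assignment_draws=np.stack(all_z),
        class_probs=class_probs, mastery_probs=mastery, profiles=profiles,
        item_slices=item_slices, item_structures=list(structures or []),
        acceptance=acceptance, seed=seed, n_free_params=n_free)
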