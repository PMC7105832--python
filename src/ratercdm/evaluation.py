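"""Evaluation machinery: recovery metrics, fit statistics, fair scores,
and the two parameter-recovery study harnesses.

Study 1 generates dichotomous ratings under the facets-CDM (500 ratees, 10
items, 5 attributes, 10 raters with known severities) under four rating
designs and refits both the generating facets-CDM and the rater-free
standard CDM (each rater's scores treated as virtual items with identical
parameters).  Study 2 generates under the HRM-CDM with an unbiased,
moderately noisy rating stage (φ=0, ψ=0.5) on a fully crossed design with
three or six raters, and refits the HRM-CDM (rating stage clamped at truth)
against a standard CDM that treats each rater's ratings as a separate
virtual examinee and averages the attribute posteriors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp

from . import constants
from .estimators import FacetsCDM, HRMCDM, StandardCDM
from .lcdm import ItemParams, lcdm_success_prob
from .mcmc import (ChainSchedule, PosteriorSummary, REDUCED_SCHEDULE,
                   _beta_from_item_params, _build_item_structures, _Data,
                   class_loglik_facets, class_loglik_hrm, class_loglik_hrm_per_rater,
                   enumerate_profiles, hrm_log_a)
from .qmatrix import QMatrix
from .raters import RaterParams, hrm_rating_table
from .simulate import RatingsTable, SimulationConfig, simulate_facets, simulate_hrm

_ECLIP = 1e-6


# ---------------------------------------------------------------------------
# Elementary metrics


def bias_rmse(estimates: Sequence[float], truth: float) -> tuple[float, float]:
    """Bias mean(est − truth) and RMSE sqrt(mean((est − truth)²)) across replications."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size == 0:
        raise ValueError("bias_rmse needs at least one replication")
    err = estimates - truth
    return float(err.mean()), float(np.sqrt((err ** 2).mean()))


def profile_recovery_rate(estimated: np.ndarray, truth: np.ndarray) -> float:
    """Percentage of ratees whose full attribute pattern matches exactly."""
    estimated = np.asarray(estimated)
    truth = np.asarray(truth)
    if estimated.shape != truth.shape:
        raise ValueError(f"shape mismatch {estimated.shape} vs {truth.shape}")
    return 100.0 * float((estimated == truth).all(axis=1).mean())


def attribute_recovery_rate(estimated: np.ndarray, truth: np.ndarray) -> float:
    """Percentage of correctly classified single attributes (secondary metric)."""
    estimated = np.asarray(estimated)
    truth = np.asarray(truth)
    if estimated.shape != truth.shape:
        raise ValueError(f"shape mismatch {estimated.shape} vs {truth.shape}")
    return 100.0 * float((estimated == truth).mean())


def posterior_recovery_rate(class_probs: np.ndarray, truth: np.ndarray) -> float:
    """Mean posterior probability (%) assigned to each ratee's true profile.

    The soft counterpart of :func:`profile_recovery_rate`: the expected
    fraction of posterior draws whose sampled pattern matches the truth.
    Class columns follow the canonical binary-counting profile order.
    """
    truth = np.asarray(truth)
    class_probs = np.asarray(class_probs)
    K = truth.shape[1]
    weights = 2 ** np.arange(K - 1, -1, -1)
    idx = truth @ weights
    return 100.0 * float(class_probs[np.arange(truth.shape[0]), idx].mean())


# ---------------------------------------------------------------------------
# Per-draw expected scores (shared by ppp and the information criteria)


def _draw_kernels(summary: PosteriorSummary, draw: np.ndarray) -> np.ndarray:
    out = np.empty((len(summary.item_structures), summary.profiles.shape[0]))
    for j, (s, sl) in enumerate(zip(summary.item_structures, summary.item_slices)):
        out[j] = s.design @ draw[sl]
    return out


def _draw_raters(summary: PosteriorSummary, draw: np.ndarray,
                 n_raters: int) -> dict[str, np.ndarray]:
    names = summary.param_names
    idx = {name: p for p, name in enumerate(names)}
    if summary.spec.rater_model == "facets":
        return {"eta": np.array([draw[idx[f"eta[{r + 1}]"]] for r in range(n_raters)])}
    if summary.spec.rater_model == "hrm":
        phi = np.array([draw[idx[f"phi[{r + 1}]"]] for r in range(n_raters)])
        psi = np.array([draw[idx[f"psi[{r + 1}]"]] for r in range(n_raters)])
        return {"phi": phi, "psi": psi}
    return {"eta": np.zeros(n_raters)}


def _expected_scores(summary: PosteriorSummary, data: _Data, draw: np.ndarray,
                     z: np.ndarray) -> np.ndarray:
    """Model probability of score 1 for every observed cell, at one draw."""
    kernels = _draw_kernels(summary, draw)
    raters = _draw_raters(summary, draw, data.n_raters)
    if summary.spec.rater_model in ("standard", "facets"):
        return expit(kernels[data.item, z[data.ratee]] - raters["eta"][data.rater])
    table = hrm_rating_table(
        [RaterParams(severity_phi=p, variability_psi=v)
         for p, v in zip(raters["phi"], raters["psi"])])
    p1 = expit(kernels[data.item, z[data.ratee]])
    return p1 * table[data.rater, 1, 1] + (1.0 - p1) * table[data.rater, 0, 1]


@dataclass(frozen=True)
class FitReport:
    """Posterior-predictive p-value and plug-in information criteria."""

    ppp: float
    aic: float
    bic: float
    log_likelihood: float = float("nan")
    n_params: int = 0
    n_obs: int = 0


def ppp_bayesian_chisq(summary: PosteriorSummary, table: RatingsTable,
                       seed: int = 0) -> float:
    """Posterior predictive p-value of a Bayesian chi-square discrepancy.

    For each retained draw, the realized discrepancy is the standardized
    Pearson sum Σ (O − E)² / (E(1−E)) over observed cells, with E the
    model's score-1 probability at that draw; the replicated discrepancy
    uses a dataset redrawn from the same draw.  The reported value is the
    fraction of draws whose replicated discrepancy is at least as large as
    the realized one; values near 0 or 1 signal misfit.
    """
    data = _Data.from_table(table)
    rng = np.random.default_rng(seed)
    draws = summary.flat_draws
    zs = summary.class_assignment_draws.reshape(-1, data.n_ratees)
    obs = data.score.astype(float)
    exceed = 0
    for d in range(draws.shape[0]):
        e = np.clip(_expected_scores(summary, data, draws[d], zs[d]),
                    _ECLIP, 1.0 - _ECLIP)
        denom = e * (1.0 - e)
        x2_real = float((((obs - e) ** 2) / denom).sum())
        rep = (rng.random(e.size) < e).astype(float)
        x2_rep = float((((rep - e) ** 2) / denom).sum())
        exceed += int(x2_rep >= x2_real)
    return exceed / draws.shape[0]


def _marginal_loglik(summary: PosteriorSummary, table: RatingsTable) -> float:
    """Observed-data log-likelihood at the EAP estimates, classes marginalized."""
    data = _Data.from_table(table)
    eap = summary.eap
    kernels = _draw_kernels(summary, eap)
    raters = _draw_raters(summary, eap, data.n_raters)
    if summary.spec.rater_model in ("standard", "facets"):
        n_pairs = data.n_items * data.n_raters
        pair = data.item * data.n_raters + data.rater
        d_obs = np.zeros((data.n_ratees, n_pairs))
        d_obs[data.ratee, pair] = 1.0
        d_one = np.zeros((data.n_ratees, n_pairs))
        d_one[data.ratee, pair] = data.score.astype(float)
        ll = class_loglik_facets(data, kernels, raters["eta"], d_obs, d_one)
    else:
        table_r = hrm_rating_table(
            [RaterParams(severity_phi=p, variability_psi=v)
             for p, v in zip(raters["phi"], raters["psi"])])
        if summary.spec.xi_structure == "per_rater":
            n_pairs = data.n_items * data.n_raters
            pair = data.item * data.n_raters + data.rater
            d_obs = np.zeros((data.n_ratees, n_pairs))
            d_obs[data.ratee, pair] = 1.0
            d_one = np.zeros((data.n_ratees, n_pairs))
            d_one[data.ratee, pair] = data.score.astype(float)
            ll = class_loglik_hrm_per_rater(data, kernels, table_r, d_obs, d_one)
        else:
            ll = class_loglik_hrm(kernels, hrm_log_a(data, table_r))
    log_pi = np.log(np.clip(summary.eap_class_weights(), 1e-300, 1.0))
    return float(logsumexp(ll + log_pi[None, :], axis=1).sum())


def aic_bic(summary: PosteriorSummary, table: RatingsTable) -> tuple[float, float]:
    """Plug-in AIC and BIC: −2ℓ(EAP) + penalty, ℓ marginal over latent classes.

    The free-parameter count covers item weights, estimated rater parameters
    (one severity lost to the zero-mean constraint in the facets model) and
    the 2^K − 1 class weights; n is the number of observed scores.
    """
    ll = _marginal_loglik(summary, table)
    p = summary.n_free_params
    n = len(table)
    return -2.0 * ll + 2.0 * p, -2.0 * ll + p * float(np.log(n))


def fit_report(summary: PosteriorSummary, table: RatingsTable,
               seed: int = 0) -> FitReport:
    ll = _marginal_loglik(summary, table)
    aic, bic = aic_bic(summary, table)
    return FitReport(ppp=ppp_bayesian_chisq(summary, table, seed=seed),
                     aic=aic, bic=bic, log_likelihood=ll,
                     n_params=summary.n_free_params, n_obs=len(table))


# ---------------------------------------------------------------------------
# Fair scores


def fair_score(profile: Sequence[int], item_params: Sequence[ItemParams],
               qmatrix: QMatrix) -> float:
    """Expected total score given a profile: Σ_j P(success on j | α), rater-free."""
    return float(sum(lcdm_success_prob(p, profile, qmatrix.row(j))
                     for j, p in enumerate(item_params)))


def fair_score_table(profiles: np.ndarray, item_params: Sequence[ItemParams],
                     qmatrix: QMatrix, table: RatingsTable) -> pd.DataFrame:
    """Observed vs fair total score per ratee (difference = observed − fair).

    The observed total averages each item's scores over the raters who
    marked it, so a ratee read by one rater keeps their raw total.
    """
    per_item = table.records.groupby(["ratee", "item"])["score"].mean()
    observed = per_item.groupby("ratee").sum()
    rows = []
    for i in range(profiles.shape[0]):
        fair = fair_score(profiles[i], item_params, qmatrix)
        obs = float(observed.get(i, np.nan))
        rows.append({"ratee": i, "observed": obs, "fair": fair,
                     "difference": obs - fair})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Recovery reports and the study harnesses


@dataclass
class RecoveryReport:
    """Per-parameter bias/RMSE across replications plus profile-recovery statistics."""

    param_names: list[str]
    generating: np.ndarray
    bias: np.ndarray
    rmse: np.ndarray
    recovery_rates: np.ndarray            # per replication, % exact-match
    attribute_recovery_rates: np.ndarray  # per replication, % attribute-wise
    posterior_recovery_rates: np.ndarray = field(default_factory=lambda: np.empty(0))
    # ^ per replication: mean posterior probability of the true pattern, %

    @property
    def mean_recovery(self) -> float:
        return float(self.recovery_rates.mean())

    @property
    def mean_rmse(self) -> float:
        return float(self.rmse.mean())

    def recovery_stats(self) -> dict[str, float]:
        r = self.recovery_rates
        return {"min": float(r.min()), "max": float(r.max()),
                "mean": float(r.mean()),
                "sd": float(r.std(ddof=1)) if r.size > 1 else 0.0}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"parameter": self.param_names,
                             "generating": self.generating,
                             "bias": self.bias, "rmse": self.rmse})


def _generating_vector(item_params: Sequence[ItemParams], qmatrix: QMatrix,
                       cdm: str, eta: np.ndarray | None) -> tuple[list[str], np.ndarray]:
    structures = _build_item_structures(qmatrix, cdm, enumerate_profiles(qmatrix.n_attributes))
    names: list[str] = []
    values: list[float] = []
    for s, p in zip(structures, item_params):
        names.extend(s.names)
        values.extend(_beta_from_item_params(s, p))
    if eta is not None:
        names.extend(f"eta[{r + 1}]" for r in range(eta.size))
        values.extend(eta)
    return names, np.asarray(values)


def _recovery_report(eaps: list[dict[str, float]], recoveries: list[float],
                     attr_recoveries: list[float], names: list[str],
                     generating: np.ndarray,
                     posterior_recoveries: list[float] | None = None) -> RecoveryReport:
    bias = np.empty(len(names))
    rmse = np.empty(len(names))
    for p, name in enumerate(names):
        estimates = [e[name] for e in eaps if name in e]
        bias[p], rmse[p] = bias_rmse(estimates, generating[p])
    return RecoveryReport(list(names), generating.copy(), bias, rmse,
                          np.asarray(recoveries), np.asarray(attr_recoveries),
                          np.asarray(posterior_recoveries or []))


def _resolve_scale(scale: str, n_replications: int | None,
                   schedule: ChainSchedule | None) -> tuple[int, ChainSchedule]:
    if scale == "reduced":
        return n_replications or 5, schedule or REDUCED_SCHEDULE
    if scale == "full":
        return n_replications or 100, schedule or ChainSchedule()
    raise ValueError(f"unknown scale {scale!r}")


def run_study_one(scale: Literal["full", "reduced"] = "reduced", seed: int = 0, *,
                  designs: Sequence[str] = ("complete", "balanced", "unbalanced", "random"),
                  n_replications: int | None = None,
                  schedule: ChainSchedule | None = None,
                  ) -> dict[str, dict[str, RecoveryReport]]:
    """Facets-CDM recovery study across rating designs.

    Per replication one facets dataset is generated at the benchmark truth
    and both the facets-CDM and the virtual-items standard CDM are fitted to
    the *same* data.  Returns ``{design: {"facets": report, "standard": report}}``.
    """
    n_reps, sched = _resolve_scale(scale, n_replications, schedule)
    qmatrix = constants.STUDY_QMATRIX
    item_truth = constants.study_item_params()
    eta_truth = constants.STUDY_RATER_SEVERITIES
    rater_params = [RaterParams(severity_eta=float(e)) for e in eta_truth]
    names_f, gen_f = _generating_vector(item_truth, qmatrix, "saturated", eta_truth)
    names_s, gen_s = _generating_vector(item_truth, qmatrix, "saturated", None)
    rng = np.random.default_rng(seed)

    results: dict[str, dict[str, RecoveryReport]] = {}
    for design in designs:
        eaps: dict[str, list[dict]] = {"facets": [], "standard": []}
        recov: dict[str, list[float]] = {"facets": [], "standard": []}
        attr: dict[str, list[float]] = {"facets": [], "standard": []}
        soft: dict[str, list[float]] = {"facets": [], "standard": []}
        for _ in range(n_reps):
            data_seed = int(rng.integers(2 ** 31))
            config = SimulationConfig(qmatrix, item_truth, rater_params, "facets",
                                      design=design, seed=data_seed)
            table = simulate_facets(config)
            fits = {
                "facets": FacetsCDM(qmatrix, n_chains=sched.n_chains,
                                    n_iterations=sched.n_iterations,
                                    burn_in=sched.burn_in, thin=sched.thin,
                                    random_state=int(rng.integers(2 ** 31))),
                "standard": StandardCDM(qmatrix, marginalization="virtual_items",
                                        n_chains=sched.n_chains,
                                        n_iterations=sched.n_iterations,
                                        burn_in=sched.burn_in, thin=sched.thin,
                                        random_state=int(rng.integers(2 ** 31))),
            }
            for key, model in fits.items():
                model.fit(table)
                eaps[key].append(model.summary_.eap_dict())
                recov[key].append(profile_recovery_rate(model.profiles_,
                                                        table.true_profiles))
                attr[key].append(attribute_recovery_rate(model.profiles_,
                                                         table.true_profiles))
                soft[key].append(posterior_recovery_rate(model.class_probs_,
                                                         table.true_profiles))
        results[design] = {
            "facets": _recovery_report(eaps["facets"], recov["facets"],
                                       attr["facets"], names_f, gen_f,
                                       soft["facets"]),
            "standard": _recovery_report(eaps["standard"], recov["standard"],
                                         attr["standard"], names_s, gen_s,
                                         soft["standard"]),
        }
    return results


def run_study_two(scale: Literal["full", "reduced"] = "reduced", seed: int = 0, *,
                  rater_counts: Sequence[int] = (3, 6),
                  n_replications: int | None = None,
                  schedule: ChainSchedule | None = None,
                  ) -> dict[int, dict[str, RecoveryReport]]:
    """HRM-CDM recovery study: fully crossed design, three vs six raters.

    Generation and the HRM refit both use the unbiased rating stage (φ = 0,
    ψ = 0.5); the rating-stage parameters are clamped at those values during
    fitting.  Each rater judges an independently realized ideal category
    (``shared_xi=False``) — the configuration under which more raters keep
    adding profile information, which is what this study varies — while the
    fitted HRM keeps its defining one-category-per-item structure
    (``xi_structure="shared"``).  The standard-CDM comparator stacks each
    rater's ratings as a virtual examinee and averages attribute posteriors
    before classifying.
    Returns ``{n_raters: {"hrm": report, "standard": report}}``.
    """
    n_reps, sched = _resolve_scale(scale, n_replications, schedule)
    qmatrix = constants.STUDY_QMATRIX
    item_truth = constants.study_item_params()
    names_h, gen_h = _generating_vector(item_truth, qmatrix, "saturated", None)
    rng = np.random.default_rng(seed)

    results: dict[int, dict[str, RecoveryReport]] = {}
    for n_raters in rater_counts:
        rater_params = [RaterParams(severity_phi=constants.HRM_STUDY_PHI,
                                    variability_psi=constants.HRM_STUDY_PSI)
                        for _ in range(n_raters)]
        eaps: dict[str, list[dict]] = {"hrm": [], "standard": []}
        recov: dict[str, list[float]] = {"hrm": [], "standard": []}
        attr: dict[str, list[float]] = {"hrm": [], "standard": []}
        soft: dict[str, list[float]] = {"hrm": [], "standard": []}
        for _ in range(n_reps):
            data_seed = int(rng.integers(2 ** 31))
            config = SimulationConfig(qmatrix, item_truth, rater_params, "hrm",
                                      design="complete", seed=data_seed,
                                      shared_xi=False)
            table = simulate_hrm(config)
            fits = {
                "hrm": HRMCDM(qmatrix, fix_rater_params=rater_params,
                              xi_structure="shared",
                              n_chains=sched.n_chains,
                              n_iterations=sched.n_iterations,
                              burn_in=sched.burn_in, thin=sched.thin,
                              random_state=int(rng.integers(2 ** 31))),
                "standard": StandardCDM(qmatrix, marginalization="virtual_examinees",
                                        n_chains=sched.n_chains,
                                        n_iterations=sched.n_iterations,
                                        burn_in=sched.burn_in, thin=sched.thin,
                                        random_state=int(rng.integers(2 ** 31))),
            }
            for key, model in fits.items():
                model.fit(table)
                eaps[key].append(model.summary_.eap_dict())
                recov[key].append(profile_recovery_rate(model.profiles_,
                                                        table.true_profiles))
                attr[key].append(attribute_recovery_rate(model.profiles_,
                                                         table.true_profiles))
                soft[key].append(posterior_recovery_rate(model.class_probs_,
                                                         table.true_profiles))
        results[n_raters] = {
            "hrm": _recovery_report(eaps["hrm"], recov["hrm"], attr["hrm"],
                                    names_h, gen_h, soft["hrm"]),
            "standard": _recovery_report(eaps["standard"], recov["standard"],
                                         attr["standard"], names_h, gen_h,
                                         soft["standard"]),
        }
    return results


def study_report_frame(results: dict) -> pd.DataFrame:
    """Flatten study results to a long CSV-ready frame (one row per parameter)."""
    rows = []
    for condition, fits in results.items():
        for model, report in fits.items():
            frame = report.to_frame()
            frame.insert(0, "condition", str(condition))
            frame.insert(1, "model", model)
            rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def study_recovery_frame(results: dict) -> pd.DataFrame:
    """Profile-recovery summary (min/max/mean/SD across replications) per condition."""
    rows = []
    for condition, fits in results.items():
        for model, report in fits.items():
            stats = report.recovery_stats()
            stats.update({"condition": str(condition), "model": model,
                          "mean_attribute_recovery":
                              float(report.attribute_recovery_rates.mean()),
                          "mean_posterior_recovery":
                              float(report.posterior_recovery_rates.mean())
                              if report.posterior_recovery_rates.size else float("nan"),
                          "mean_rmse": report.mean_rmse})
            rows.append(stats)
    return pd.DataFrame(rows)[["condition", "model", "min", "max", "mean", "sd",
                               "mean_attribute_recovery",
                               "mean_posterior_recovery", "mean_rmse"]]
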