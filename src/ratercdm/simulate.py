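"""Synthetic rating data: attribute profiles, rating designs, and scores.

Profiles are generated by thresholding correlated multivariate-normal
abilities: ratee *i* masters attribute *k* iff θ_ik ≥ Φ⁻¹(k / (K+1)), with
θ ~ MVN(0, Σ), unit variances and a common inter-attribute correlation ρ.
The thresholds rise with the attribute index, so attribute k has marginal
mastery rate 1 − k/(K+1) — early attributes are easy, later ones rare.

Rating designs decide which raters judge which ratees.  Four kinds are
supported: *complete* (fully crossed), *balanced* incomplete (rotating
blocks, every rater judges the same number of ratees), *unbalanced*
incomplete (same rotation, unequal block sizes), and *random* (a small
fully-crossed anchor set plus three randomly drawn raters per remaining
ratee).  All four leave the rater–ratee graph connected, which is what
makes rater severities comparable across the pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import expit
from scipy.stats import norm

from . import constants
from .lcdm import ItemParams, kernel_table, success_prob_table
from .qmatrix import QMatrix
from .raters import RaterParams, hrm_rating_table

DesignKind = Literal["complete", "balanced", "unbalanced", "random"]


@dataclass
class RatingDesign:
    """Ratee × rater assignment: ``assignment[i, r]`` is True when rater r judges ratee i."""

    assignment: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=bool)
        if a.ndim != 2:
            raise ValueError("assignment must be a ratee × rater matrix")
        orphans = np.flatnonzero(~a.any(axis=1))
        if orphans.size:
            raise ValueError(f"ratees {orphans[:5].tolist()} have no rater")
        self.assignment = a

    @property
    def n_ratees(self) -> int:
        return self.assignment.shape[0]

    @property
    def n_raters(self) -> int:
        return self.assignment.shape[1]

    @property
    def n_pairs(self) -> int:
        return int(self.assignment.sum())

    def raters_of(self, ratee: int) -> np.ndarray:
        return np.flatnonzero(self.assignment[ratee])

    def is_connected(self) -> bool:
        """True when all raters are linked through shared ratees."""
        i, r = np.nonzero(self.assignment)
        n, m = self.assignment.shape
        graph = coo_matrix((np.ones_like(i), (i, n + r)), shape=(n + m, n + m))
        n_comp, _ = connected_components(graph, directed=False)
        return n_comp == 1


@dataclass
class RatingsTable:
    """Long-format dichotomous ratings plus (for synthetic data) the truth.

    ``records`` has integer columns ``ratee, item, rater, score``; one row
    per permitted (ratee, item, rater) triple.  ``true_profiles`` holds the
    generating attribute profiles; ``true_xi`` the latent ideal categories
    of HRM-generated data (N × J); ``true_theta`` the underlying abilities.
    """

    records: pd.DataFrame
    n_ratees: int
    n_items: int
    n_raters: int
    true_profiles: np.ndarray | None = None
    true_theta: np.ndarray | None = None
    true_xi: np.ndarray | None = None
    id_maps: dict | None = None  # opaque external ids -> dense indices, per column

    def __post_init__(self) -> None:
        required = ["ratee", "item", "rater", "score"]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise ValueError(f"records missing columns {missing}")
        scores = self.records["score"].to_numpy()
        if not np.isin(scores, (0, 1)).all():
            raise ValueError("scores must be binary")
        if self.records.duplicated(["ratee", "item", "rater"]).any():
            raise ValueError("duplicate (ratee, item, rater) triples")

    def __len__(self) -> int:
        return len(self.records)

    def rater_means(self) -> pd.Series:
        return self.records.groupby("rater")["score"].mean()


@dataclass
class SimulationConfig:
    """One synthetic-data condition: who is measured, by whom, under which model."""

    qmatrix: QMatrix
    item_params: Sequence[ItemParams]
    rater_params: Sequence[RaterParams]
    model: Literal["facets", "hrm"]
    design: DesignKind | RatingDesign = "complete"
    n_ratees: int = constants.STUDY_N_RATEES
    rho: float = constants.STUDY_RHO
    seed: int = 0
    # HRM only: one shared ideal category per (ratee, item) — the HRM premise —
    # or an independent realization per rater (each rater judges an
    # independently produced response, as in a multiple-independent-responses
    # recovery design).
    shared_xi: bool = True

    def __post_init__(self) -> None:
        if len(self.item_params) != self.qmatrix.n_items:
            raise ValueError("item_params length does not match the Q-matrix")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if self.model not in ("facets", "hrm"):
            raise ValueError(f"unknown model {self.model!r}")


def generate_profiles(n_ratees: int, n_attributes: int, rho: float,
                      seed: int | np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw binary attribute profiles by thresholding correlated normal abilities.

    Returns ``(profiles, theta)``: profiles of shape (N, K) in {0,1} and the
    underlying ability draws.  ``alpha[i, k] = 1`` iff
    ``theta[i, k] >= norm.ppf((k+1) / (K+1))`` (attributes indexed from 0).
    """
    if n_ratees < 1 or n_attributes < 1:
        raise ValueError("n_ratees and n_attributes must be ≥ 1")
    if not 0 <= rho < 1:
        raise ValueError(f"rho must be in [0, 1) (got {rho})")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cov = np.full((n_attributes, n_attributes), rho)
    np.fill_diagonal(cov, 1.0)
    # rho in [0,1) keeps cov positive definite; assert anyway.
    if np.linalg.eigvalsh(cov).min() <= 0:
        raise ValueError("covariance matrix is not positive definite")
    theta = rng.multivariate_normal(np.zeros(n_attributes), cov, size=n_ratees,
                                    method="cholesky")
    thresholds = mastery_thresholds(n_attributes)
    profiles = (theta >= thresholds).astype(np.int8)
    return profiles, theta


def mastery_thresholds(n_attributes: int) -> np.ndarray:
    """Ability cutoffs Φ⁻¹(k/(K+1)), k = 1..K."""
    k = np.arange(1, n_attributes + 1)
    return norm.ppf(k / (n_attributes + 1))


def _rotating_blocks(n_ratees: int, n_raters: int,
                     block_sizes: Sequence[int]) -> np.ndarray:
    triples = [(b % n_raters, (b + 1) % n_raters, (b + 2) % n_raters)
               for b in range(len(block_sizes))]
    if n_ratees == constants.STUDY_N_RATEES and n_raters == 10:
        triples = constants.BLOCK_RATER_TRIPLES
    assignment = np.zeros((n_ratees, n_raters), dtype=bool)
    start = 0
    for size, triple in zip(block_sizes, triples):
        assignment[start:start + size, list(triple)] = True
        start += size
    return assignment


def build_design(kind: DesignKind, n_ratees: int, n_raters: int,
                 seed: int | np.random.Generator = 0) -> RatingDesign:
    """Construct a rating design of the given kind.

    For 500 ratees and 10 raters the balanced and unbalanced kinds reproduce
    the benchmark block layout exactly (balanced: every rater judges 150
    ratees; unbalanced: column totals 139, 167, 162, 170, 137, 144, 136,
    156, 145, 144).  Other sizes reuse the same rotating three-rater block
    scheme, with near-equal blocks (balanced) or a fixed ±jitter pattern
    renormalized to N (unbalanced).
    """
    if kind == "complete":
        return RatingDesign(np.ones((n_ratees, n_raters), dtype=bool), kind)
    if n_raters < 3:
        raise ValueError(f"{kind} design needs ≥3 raters to give each ratee 3 raters")

    if kind in ("balanced", "unbalanced"):
        if n_ratees == constants.STUDY_N_RATEES and n_raters == 10:
            sizes = (constants.BALANCED_BLOCK_SIZES if kind == "balanced"
                     else constants.UNBALANCED_BLOCK_SIZES)
        else:
            base = np.full(n_raters, n_ratees // n_raters)
            base[: n_ratees % n_raters] += 1
            if kind == "unbalanced":
                jitter = np.round(base * 0.2 * np.cos(np.arange(n_raters))).astype(int)
                jitter -= jitter.sum() // n_raters
                base = base + jitter
                base[base < 1] = 1
                base[-1] += n_ratees - base.sum()
            sizes = base.tolist()
        if sum(sizes) != n_ratees:
            raise ValueError(f"{kind} block sizes {sizes} do not cover {n_ratees} ratees")
        design = RatingDesign(_rotating_blocks(n_ratees, n_raters, sizes), kind)
    elif kind == "random":
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        n_anchor = min(constants.RANDOM_DESIGN_ANCHORS, n_ratees)
        assignment = np.zeros((n_ratees, n_raters), dtype=bool)
        assignment[:n_anchor] = True
        for i in range(n_anchor, n_ratees):
            chosen = rng.choice(n_raters, size=constants.INCOMPLETE_RATERS_PER_RATEE,
                                replace=False)
            assignment[i, chosen] = True
        design = RatingDesign(assignment, kind)
    else:
        raise ValueError(f"unknown design kind {kind!r}")

    if not design.is_connected():
        raise ValueError(
            f"{kind} design with N={n_ratees}, R={n_raters} leaves the rater pool "
            f"disconnected; severities would not be comparable")
    return design


def _resolve_design(config: SimulationConfig) -> RatingDesign:
    if isinstance(config.design, RatingDesign):
        return config.design
    return build_design(config.design, config.n_ratees, len(config.rater_params),
                        np.random.default_rng((config.seed, 0x0DE51F)))


def _records_from_scores(design: RatingDesign, scores: np.ndarray,
                         n_items: int) -> pd.DataFrame:
    """Flatten an (N, J, R) score array to long format along the design mask."""
    i_idx, r_idx = np.nonzero(design.assignment)
    ratee = np.repeat(i_idx, n_items)
    rater = np.repeat(r_idx, n_items)
    item = np.tile(np.arange(n_items), i_idx.size)
    return pd.DataFrame({
        "ratee": ratee, "item": item, "rater": rater,
        "score": scores[ratee, item, rater].astype(np.int8),
    })


def simulate_facets(config: SimulationConfig) -> RatingsTable:
    """Generate ratings under the facets-CDM: score ~ Bernoulli(logistic(kernel − η_r))."""
    if config.model != "facets":
        raise ValueError("config.model must be 'facets'")
    rng = np.random.default_rng(config.seed)
    K = config.qmatrix.n_attributes
    profiles, theta = generate_profiles(config.n_ratees, K, config.rho, rng)
    design = _resolve_design(config)
    kernels = kernel_table(config.item_params, config.qmatrix)  # (J, C)
    weights = 2 ** np.arange(K - 1, -1, -1)
    classes = profiles @ weights  # canonical class index per ratee
    eta = np.array([r.severity_eta for r in config.rater_params])
    # (N, J, R) success probabilities, then one Bernoulli draw per cell.
    prob = expit(kernels[:, classes].T[:, :, None] - eta[None, None, :])
    scores = (rng.random(prob.shape) < prob).astype(np.int8)
    records = _records_from_scores(design, scores, config.qmatrix.n_items)
    return RatingsTable(records, config.n_ratees, config.qmatrix.n_items,
                        len(config.rater_params),
                        true_profiles=profiles, true_theta=theta)


def simulate_hrm(config: SimulationConfig) -> RatingsTable:
    """Generate ratings under the HRM-CDM.

    Stage 1 draws the ideal category ξ from the latent LCDM — by default one
    shared ξ_ij per (ratee, item), so raters of the same response are
    conditionally independent given ξ but marginally correlated through it.
    With ``config.shared_xi=False`` each rater instead judges an
    independently realized category ξ_ijr (every rater sees an independent
    response), which makes raters marginally independent.  Stage 2 passes ξ
    through each assigned rater's signal-detection kernel.
    """
    if config.model != "hrm":
        raise ValueError("config.model must be 'hrm'")
    rng = np.random.default_rng(config.seed)
    K = config.qmatrix.n_attributes
    profiles, theta = generate_profiles(config.n_ratees, K, config.rho, rng)
    design = _resolve_design(config)
    p_xi = success_prob_table(config.item_params, config.qmatrix)  # (J, C)
    weights = 2 ** np.arange(K - 1, -1, -1)
    classes = profiles @ weights
    n_raters = len(config.rater_params)
    table = hrm_rating_table(config.rater_params)  # (R, xi, k)
    p_score1 = table[:, :, 1]  # (R, xi)
    if config.shared_xi:
        xi = (rng.random((config.n_ratees, config.qmatrix.n_items))
              < p_xi[:, classes].T).astype(np.int8)
        prob = p_score1.T[xi]  # (N, J, R) via xi indexing rows of (xi, R)
    else:
        xi = (rng.random((config.n_ratees, config.qmatrix.n_items, n_raters))
              < p_xi[:, classes].T[:, :, None]).astype(np.int8)
        prob = np.where(xi == 1, p_score1[:, 1], p_score1[:, 0])
    scores = (rng.random(prob.shape) < prob).astype(np.int8)
    records = _records_from_scores(design, scores, config.qmatrix.n_items)
    return RatingsTable(records, config.n_ratees, config.qmatrix.n_items,
                        len(config.rater_params),
                        true_profiles=profiles, true_theta=theta, true_xi=xi)


def simulate(config: SimulationConfig) -> RatingsTable:
    """Dispatch on ``config.model``."""
    return simulate_facets(config) if config.model == "facets" else simulate_hrm(config)


@dataclass
class ChecklistFixture:
    """Synthetic checklist-marking dataset shaped like a realistic essay study."""

    ratings: RatingsTable
    qmatrix: QMatrix
    item_params: list[ItemParams] = field(default_factory=list)
    rater_params: list[RaterParams] = field(default_factory=list)


def generate_checklist_fixture(seed: int = 0) -> ChecklistFixture:
    """Synthetic 287-ratee × 52-item × 9-rater checklist dataset.

    Scores are generated under the HRM-DINA: DINA item parameters with
    moderate guessing and slip, six writing attributes, the checklist
    Q-matrix, and a rater pool whose severities and variabilities span the
    realistic range (two severe raters, variabilities 0.37–1.28).  Each
    essay is read by one or two raters.
    """
    rng = np.random.default_rng(seed)
    qmatrix = constants.CHECKLIST_QMATRIX
    J = qmatrix.n_items
    guessing = rng.uniform(0.05, 0.40, size=J)
    slip = rng.uniform(0.05, 0.40, size=J)
    item_params = [
        ItemParams.dina(float(np.log(g / (1 - g))),
                        float(np.log((1 - s) / s) - np.log(g / (1 - g))),
                        qmatrix.required(j))
        for j, (g, s) in enumerate(zip(guessing, slip))
    ]
    rater_params = [RaterParams(severity_phi=float(phi), variability_psi=float(psi))
                    for phi, psi in zip(constants.CHECKLIST_RATER_PHI,
                                        constants.CHECKLIST_RATER_PSI)]
    N, R = constants.CHECKLIST_N_RATEES, constants.CHECKLIST_N_RATERS
    assignment = np.zeros((N, R), dtype=bool)
    for i in range(N):
        n_readers = int(rng.integers(1, 3))  # 1 or 2 raters per essay
        assignment[i, rng.choice(R, size=n_readers, replace=False)] = True
    design = RatingDesign(assignment, "random")
    config = SimulationConfig(qmatrix, item_params, rater_params, "hrm",
                              design=design, n_ratees=N, rho=constants.STUDY_RHO,
                              seed=int(rng.integers(2 ** 31)))
    return ChecklistFixture(simulate_hrm(config), qmatrix, item_params, rater_params)
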