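"""Log-linear cognitive diagnosis model (LCDM) measurement kernel.

The LCDM expresses the log-odds of success on item *j* for a ratee with
binary attribute profile α as an intercept plus main effects of the
attributes the item requires plus interaction effects among them::

    logit P(X_j = 1 | α) = λ_j0 + Σ_k λ_jk α_k q_jk + Σ_{k<v} λ_jkv α_k α_v q_jk q_jv + ...

Positive main effects give the monotone ordering that makes attribute
mastery interpretable.  The DINA model is the constrained special case in
which only the intercept and the single highest-order interaction over all
required attributes are free, so each item takes exactly two distinct
success probabilities: "guessing" for profiles missing any required
attribute and one minus "slip" for profiles mastering all of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import expit

from .qmatrix import QMatrix

MAX_ATTRIBUTES = 15

SATURATED = "saturated-LCDM"
DINA = "DINA"


@dataclass(frozen=True)
class ItemParams:
    """Weights of one item's LCDM kernel.

    ``main_effects`` maps required-attribute indices to main-effect weights;
    ``interactions`` maps sorted tuples of two or more required-attribute
    indices to interaction weights.  ``constraint_tag`` is ``"saturated-LCDM"``
    or ``"DINA"``; a DINA item carries no main effects beyond the single
    highest-order term (a one-attribute DINA item keeps that term as the
    main effect — the two forms coincide there).
    """

    intercept: float
    main_effects: Mapping[int, float] = field(default_factory=dict)
    interactions: Mapping[tuple[int, ...], float] = field(default_factory=dict)
    constraint_tag: str = SATURATED

    def __post_init__(self) -> None:
        object.__setattr__(self, "main_effects", dict(self.main_effects))
        inter = {}
        for key, value in dict(self.interactions).items():
            key = tuple(sorted(int(k) for k in key))
            if len(key) < 2:
                raise ValueError(f"interaction key {key} must involve ≥2 attributes")
            if len(set(key)) != len(key):
                raise ValueError(f"interaction key {key} repeats an attribute")
            inter[key] = float(value)
        object.__setattr__(self, "interactions", inter)
        if self.constraint_tag not in (SATURATED, DINA):
            raise ValueError(f"unknown constraint tag {self.constraint_tag!r}")

    @classmethod
    def dina(cls, intercept: float, top_effect: float, required: Sequence[int]) -> "ItemParams":
        """DINA item: intercept plus the conjunctive top-order term over ``required``."""
        required = tuple(sorted(int(k) for k in required))
        if not required:
            raise ValueError("a DINA item needs at least one required attribute")
        if len(required) == 1:
            return cls(intercept, {required[0]: top_effect}, {}, DINA)
        return cls(intercept, {}, {required: top_effect}, DINA)

    @property
    def top_effect(self) -> float:
        """The conjunctive weight of a DINA item."""
        if self.constraint_tag != DINA:
            raise ValueError("top_effect is defined only for DINA items")
        if self.interactions:
            return next(iter(self.interactions.values()))
        return next(iter(self.main_effects.values()))


@dataclass(frozen=True)
class GuessSlip:
    """Guessing (success with incomplete mastery) and slip (failure at full mastery)."""

    guessing: float
    slip: float


def enumerate_profiles(n_attributes: int) -> np.ndarray:
    """All 2^K binary attribute profiles in canonical binary-counting order.

    Attribute 1 is the most significant bit, so for K=2 the order is
    (0,0), (0,1), (1,0), (1,1).  The order is fixed so that latent-class
    indices are stable across runs and samplers.
    """
    if not 1 <= n_attributes <= MAX_ATTRIBUTES:
        raise ValueError(
            f"n_attributes must be in [1, {MAX_ATTRIBUTES}] (got {n_attributes}); "
            f"the latent class space has 2^K cells"
        )
    grid = np.arange(2 ** n_attributes)
    shifts = n_attributes - 1 - np.arange(n_attributes)
    return ((grid[:, None] >> shifts[None, :]) & 1).astype(np.int8)


def _check_interactions(params: ItemParams, required: Iterable[int]) -> None:
    required = set(required)
    for key in params.interactions:
        if not set(key) <= required:
            raise ValueError(
                f"interaction {key} references attributes the item does not require {sorted(required)}"
            )


def lcdm_linear_predictor(params: ItemParams, alpha: Sequence[int], q_row: Sequence[int]) -> float:
    """Evaluate the LCDM kernel λ_j0 + Σ λ_jk α_k q_jk + Σ λ_jkv α_k α_v q_jk q_jv + ...

    Attributes the item does not require contribute nothing regardless of α.
    """
    alpha = np.asarray(alpha, dtype=int)
    q_row = np.asarray(q_row, dtype=int)
    if alpha.shape != q_row.shape:
        raise ValueError("alpha and q_row must have the same length")
    required = set(np.flatnonzero(q_row))
    _check_interactions(params, required)
    value = float(params.intercept)
    for k, weight in params.main_effects.items():
        if k in required and alpha[k]:
            value += weight
    for key, weight in params.interactions.items():
        if all(alpha[k] for k in key):
            value += weight
    return value


def lcdm_success_prob(params: ItemParams, alpha: Sequence[int], q_row: Sequence[int]) -> float:
    """P(score 1 | α) under the LCDM: the logistic transform of the kernel."""
    return float(expit(lcdm_linear_predictor(params, alpha, q_row)))


def dina_success_prob(params: ItemParams, alpha: Sequence[int], q_row: Sequence[int]) -> float:
    """DINA success probability: logistic(λ_j0 + λ_top · Π_{k required} α_k)."""
    if params.constraint_tag != DINA:
        raise ValueError("dina_success_prob requires DINA-constrained ItemParams")
    alpha = np.asarray(alpha, dtype=int)
    q_row = np.asarray(q_row, dtype=int)
    mastered_all = bool(np.all(alpha[q_row == 1] == 1))
    return float(expit(params.intercept + (params.top_effect if mastered_all else 0.0)))


def guessing_slip(params: ItemParams, q_row: Sequence[int]) -> GuessSlip:
    """Reparameterize one item's kernel as guessing and slip probabilities.

    Guessing is the success probability of the no-mastery profile,
    logistic(λ_j0); slip is one minus the success probability of the profile
    mastering every required attribute.
    """
    q_row = np.asarray(q_row, dtype=int)
    full = np.ones_like(q_row)
    return GuessSlip(
        guessing=float(expit(params.intercept)),
        slip=1.0 - lcdm_success_prob(params, full, q_row),
    )


def kernel_table(item_params: Sequence[ItemParams], qmatrix: QMatrix,
                 profiles: np.ndarray | None = None) -> np.ndarray:
    """Linear predictors for every item at every latent class.

    Returns an array of shape ``(n_items, n_classes)``; ``profiles`` defaults
    to :func:`enumerate_profiles` in canonical order.  This is the hot-path
    form of the kernel used by the simulator and the sampler.
    """
    if profiles is None:
        profiles = enumerate_profiles(qmatrix.n_attributes)
    if len(item_params) != qmatrix.n_items:
        raise ValueError("item_params length does not match the Q-matrix")
    out = np.empty((qmatrix.n_items, profiles.shape[0]))
    for j, params in enumerate(item_params):
        q_row = qmatrix.row(j)
        required = set(np.flatnonzero(q_row))
        _check_interactions(params, required)
        values = np.full(profiles.shape[0], float(params.intercept))
        for k, weight in params.main_effects.items():
            if k in required:
                values += weight * profiles[:, k]
        for key, weight in params.interactions.items():
            values += weight * profiles[:, key].prod(axis=1)
        out[j] = values
    return out


def success_prob_table(item_params: Sequence[ItemParams], qmatrix: QMatrix,
                       profiles: np.ndarray | None = None) -> np.ndarray:
    """Success probabilities per (item, latent class); logistic of :func:`kernel_table`."""
    return expit(kernel_table(item_params, qmatrix, profiles))
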