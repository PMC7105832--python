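"""Rater-effect extensions of the LCDM.

Two ways of letting human raters into a cognitive diagnosis model:

* **Facets**: each rater carries an additive severity η_r inside the logit,
  ``logit P(score 1) = λ_j0 − η_r + kernel(α)``.  Positive severity lowers
  the chance of a favourable score; with all η_r = 0 the model collapses to
  the standard LCDM.  More raters mean more measurements and more precision.

* **HRM (hierarchical rater model)**: raters are noisy readouts of a latent
  *ideal* binary category ξ_ij, itself governed by an LCDM.  The rating
  stage is a discretized normal signal-detection kernel,
  ``P(k | ξ) ∝ exp(−(k − (ξ − φ_r))² / (2 ψ_r²))`` normalized over k ∈ {0,1},
  with severity φ_r shifting the perceived category and variability ψ_r
  blurring it.  Because all raters read the same ξ, extra raters sharpen the
  reconstruction of ξ but cannot add information beyond it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit

from .lcdm import ItemParams, lcdm_success_prob


@dataclass(frozen=True)
class RaterParams:
    """Per-rater parameters: facets severity η, HRM severity φ and variability ψ."""

    severity_eta: float = 0.0
    severity_phi: float = 0.0
    variability_psi: float = 1.0

    def __post_init__(self) -> None:
        if not self.variability_psi > 0:
            raise ValueError(f"variability_psi must be > 0 (got {self.variability_psi})")


def facets_success_prob(params: ItemParams, eta: float, alpha: Sequence[int],
                        q_row: Sequence[int]) -> float:
    """P(score 1 | α, rater) under the facets-CDM: logistic(kernel − η_r)."""
    from .lcdm import lcdm_linear_predictor

    return float(expit(lcdm_linear_predictor(params, alpha, q_row) - eta))


def hrm_rating_prob(xi: int, rater: RaterParams) -> np.ndarray:
    """Rating-stage distribution [P(k=0|ξ), P(k=1|ξ)] for one rater.

    The normal-density signal-detection kernel of the HRM, normalized over
    the two admissible scores of a dichotomous item.
    """
    if xi not in (0, 1):
        raise ValueError(f"latent category must be 0 or 1 (got {xi})")
    if not rater.variability_psi > 0:
        raise ValueError("variability_psi must be > 0")
    k = np.array([0.0, 1.0])
    centre = xi - rater.severity_phi
    log_weights = -((k - centre) ** 2) / (2.0 * rater.variability_psi ** 2)
    log_weights -= log_weights.max()  # overflow guard; normalization absorbs it
    weights = np.exp(log_weights)
    return weights / weights.sum()


def hrm_rating_table(raters: Sequence[RaterParams]) -> np.ndarray:
    """Rating-stage probabilities for a rater pool, shape (n_raters, ξ∈{0,1}, k∈{0,1})."""
    table = np.empty((len(raters), 2, 2))
    for r, rater in enumerate(raters):
        table[r, 0] = hrm_rating_prob(0, rater)
        table[r, 1] = hrm_rating_prob(1, rater)
    return table


def hrm_latent_category_prob(params: ItemParams, alpha: Sequence[int],
                             q_row: Sequence[int]) -> float:
    """P(ξ_ij = 1 | α): the LCDM applied to the latent ideal category."""
    return lcdm_success_prob(params, alpha, q_row)


def hrm_marginal_observed_prob(params: ItemParams, alpha: Sequence[int],
                               q_row: Sequence[int], rater: RaterParams) -> float:
    """P(observed score 1 | α, rater), marginalizing the latent category ξ."""
    p_xi1 = hrm_latent_category_prob(params, alpha, q_row)
    p_k1_given_xi1 = hrm_rating_prob(1, rater)[1]
    p_k1_given_xi0 = hrm_rating_prob(0, rater)[1]
    return p_xi1 * p_k1_given_xi1 + (1.0 - p_xi1) * p_k1_given_xi0
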