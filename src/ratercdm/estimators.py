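"""Scikit-learn-style estimators for CDMs with rater effects.

`StandardCDM`, `FacetsCDM` and `HRMCDM` wrap the Metropolis-within-Gibbs
engine behind the familiar ``fit`` / fitted-attribute / ``get_params``
surface, so they compose with sklearn tooling.  ``X`` is a long-format
ratings table — a DataFrame with integer columns ``ratee, item, rater,
score`` or a :class:`~ratercdm.simulate.RatingsTable` — and the "labels"
the models produce are per-ratee binary attribute profiles.

Example
-------
>>> from ratercdm import FacetsCDM, constants, simulate
>>> cfg = simulate.SimulationConfig(constants.STUDY_QMATRIX,
...     constants.study_item_params(),
...     [simulate.RaterParams(severity_eta=e) for e in constants.STUDY_RATER_SEVERITIES],
...     "facets", seed=1)
>>> model = FacetsCDM(constants.STUDY_QMATRIX, n_iterations=2000, burn_in=1000)
>>> profiles = model.fit(simulate.simulate_facets(cfg)).predict()
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import mcmc
from .qmatrix import QMatrix
from .raters import RaterParams
from .simulate import RatingsTable


def as_ratings_table(X) -> RatingsTable:
    """Coerce a long-format DataFrame (or pass through a RatingsTable)."""
    if isinstance(X, RatingsTable):
        return X
    frame = pd.DataFrame(X)
    return RatingsTable(
        frame,
        n_ratees=int(frame["ratee"].max()) + 1,
        n_items=int(frame["item"].max()) + 1,
        n_raters=int(frame["rater"].max()) + 1,
    )


def stack_virtual_examinees(table: RatingsTable) -> tuple[RatingsTable, np.ndarray]:
    """Re-index each (ratee, rater) pair as its own single-rater examinee.

    Returns the restacked table and an array mapping every virtual examinee
    back to its original ratee, for posterior averaging.
    """
    rec = table.records
    pair_codes, origin_pairs = pd.factorize(
        rec["ratee"].astype(np.int64) * table.n_raters + rec["rater"].astype(np.int64))
    stacked = pd.DataFrame({
        "ratee": pair_codes,
        "item": rec["item"].to_numpy(),
        "rater": 0,
        "score": rec["score"].to_numpy(),
    })
    origin = (np.asarray(origin_pairs) // table.n_raters).astype(np.int64)
    return (RatingsTable(stacked, n_ratees=len(origin_pairs),
                         n_items=table.n_items, n_raters=1), origin)


class _BaseCDMEstimator(BaseEstimator):
    _rater_model = "standard"

    def __init__(self, qmatrix: QMatrix | None = None, *, cdm: str = "saturated",
                 n_chains: int = 2, n_iterations: int = 10_000, burn_in: int = 5_000,
                 thin: int = 10, priors: mcmc.PriorSpec | None = None,
                 random_state: int = 0):
        self.qmatrix = qmatrix
        self.cdm = cdm
        self.n_chains = n_chains
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.thin = thin
        self.priors = priors
        self.random_state = random_state

    def _schedule(self) -> mcmc.ChainSchedule:
        return mcmc.ChainSchedule(self.n_chains, self.n_iterations, self.burn_in,
                                  self.thin)

    def _spec(self) -> mcmc.ModelSpec:
        return mcmc.ModelSpec(self._rater_model, self.cdm)

    def _fit_kwargs(self) -> dict:
        return {}

    def fit(self, X, y=None):
        """Run the sampler on a long-format ratings table."""
        if self.qmatrix is None:
            raise ValueError("qmatrix must be provided before fitting")
        table = as_ratings_table(X)
        self.summary_ = mcmc.fit(self._spec(), table, self.qmatrix,
                                 priors=self.priors, schedule=self._schedule(),
                                 seed=self.random_state, **self._fit_kwargs())
        self._finalize(table)
        return self

    def _finalize(self, table: RatingsTable) -> None:
        s = self.summary_
        self.mastery_probs_ = s.mastery_probs
        self.class_probs_ = s.class_probs
        self.profiles_ = mcmc.classify_profiles(s.mastery_probs)
        self.item_params_ = s.eap_item_params()
        self.rater_params_ = s.eap_rater_params()
        self.class_weights_ = s.eap_class_weights()
        self.rhat_ = dict(zip(s.param_names, s.rhat))
        self.n_features_in_ = 4

    def predict(self, X=None) -> np.ndarray:
        """Classified attribute profiles of the fitted ratees (N × K in {0,1})."""
        if not hasattr(self, "profiles_"):
            raise ValueError("estimator is not fitted; call fit first")
        return self.profiles_

    def predict_proba(self, X=None) -> np.ndarray:
        """Posterior attribute-mastery probabilities of the fitted ratees."""
        if not hasattr(self, "mastery_probs_"):
            raise ValueError("estimator is not fitted; call fit first")
        return self.mastery_probs_


class StandardCDM(_BaseCDMEstimator):
    """Rater-free LCDM/DINA baseline.

    Under ``marginalization="virtual_items"`` each rater's column of scores
    is treated as an extra copy of the item with identical parameters (no
    rater terms); under ``"virtual_examinees"`` each (ratee, rater) pair is
    fitted as a separate examinee and the attribute posteriors are averaged
    across a ratee's virtual copies before classification.
    """

    _rater_model = "standard"

    def __init__(self, qmatrix: QMatrix | None = None, *, cdm: str = "saturated",
                 marginalization: str = "virtual_items", n_chains: int = 2,
                 n_iterations: int = 10_000, burn_in: int = 5_000, thin: int = 10,
                 priors: mcmc.PriorSpec | None = None, random_state: int = 0):
        super().__init__(qmatrix, cdm=cdm, n_chains=n_chains,
                         n_iterations=n_iterations, burn_in=burn_in, thin=thin,
                         priors=priors, random_state=random_state)
        if marginalization not in ("virtual_items", "virtual_examinees"):
            raise ValueError(f"unknown marginalization {marginalization!r}")
        self.marginalization = marginalization

    def fit(self, X, y=None):
        if self.qmatrix is None:
            raise ValueError("qmatrix must be provided before fitting")
        table = as_ratings_table(X)
        if self.marginalization == "virtual_items":
            return super().fit(table)
        stacked, origin = stack_virtual_examinees(table)
        self.summary_ = mcmc.fit(self._spec(), stacked, self.qmatrix,
                                 priors=self.priors, schedule=self._schedule(),
                                 seed=self.random_state)
        # Average the attribute (and class) posteriors of each ratee's
        # virtual examinees.
        K = self.qmatrix.n_attributes
        sums = np.zeros((table.n_ratees, K))
        class_sums = np.zeros((table.n_ratees, 2 ** K))
        counts = np.zeros(table.n_ratees)
        np.add.at(sums, origin, self.summary_.mastery_probs)
        np.add.at(class_sums, origin, self.summary_.class_probs)
        np.add.at(counts, origin, 1.0)
        self.virtual_origin_ = origin
        self.mastery_probs_ = sums / counts[:, None]
        self.class_probs_ = class_sums / counts[:, None]
        self.profiles_ = mcmc.classify_profiles(self.mastery_probs_)
        self.item_params_ = self.summary_.eap_item_params()
        self.rater_params_ = []
        self.class_weights_ = self.summary_.eap_class_weights()
        self.rhat_ = dict(zip(self.summary_.param_names, self.summary_.rhat))
        self.n_features_in_ = 4
        return self


class FacetsCDM(_BaseCDMEstimator):
    """Facets-CDM: additive rater severity η_r inside the LCDM logit.

    Severities are identified by the zero-mean constraint over the rater
    pool; ``rater_params_`` exposes their EAP estimates after fitting.
    """

    _rater_model = "facets"


class HRMCDM(_BaseCDMEstimator):
    """HRM-CDM: signal-detection rating stage over a latent LCDM-governed category.

    ``fix_rater_params`` clamps the rating stage (φ_r, ψ_r) at known values —
    the usual first-step configuration of a recovery study — while the
    default estimates them under N(0,1) and log-normal(0,4) priors.
    ``xi_structure`` chooses between one shared ideal category per
    (ratee, item) and an independent realization per rater.
    """

    _rater_model = "hrm"

    def __init__(self, qmatrix: QMatrix | None = None, *, cdm: str = "saturated",
                 fix_rater_params: Sequence[RaterParams] | None = None,
                 xi_structure: str = "shared",
                 n_chains: int = 2, n_iterations: int = 10_000, burn_in: int = 5_000,
                 thin: int = 10, priors: mcmc.PriorSpec | None = None,
                 random_state: int = 0):
        super().__init__(qmatrix, cdm=cdm, n_chains=n_chains,
                         n_iterations=n_iterations, burn_in=burn_in, thin=thin,
                         priors=priors, random_state=random_state)
        self.fix_rater_params = fix_rater_params
        self.xi_structure = xi_structure

    def _spec(self) -> mcmc.ModelSpec:
        return mcmc.ModelSpec("hrm", self.cdm, self.xi_structure)

    def _fit_kwargs(self) -> dict:
        return {"fix_rater_params": self.fix_rater_params}
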