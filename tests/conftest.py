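"""Shared fixtures: benchmark truths and small synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

import ratercdm as rc
from ratercdm import constants


@pytest.fixture(scope="session")
def study_qmatrix():
    return constants.STUDY_QMATRIX


@pytest.fixture(scope="session")
def study_items():
    return constants.study_item_params()


@pytest.fixture(scope="session")
def study_raters():
    return [rc.RaterParams(severity_eta=float(e))
            for e in constants.STUDY_RATER_SEVERITIES]


@pytest.fixture(scope="session")
def small_facets_table(study_qmatrix, study_items, study_raters):
    """A compact complete-design facets dataset (150 ratees) for sampler tests."""
    config = rc.SimulationConfig(study_qmatrix, study_items, study_raters,
                                 "facets", design="complete", n_ratees=150, seed=42)
    return rc.simulate_facets(config)


@pytest.fixture(scope="session")
def tiny_qmatrix():
    """Two attributes, three items: simple structure plus one two-attribute item."""
    return rc.QMatrix(np.array([[1, 0], [0, 1], [1, 1]]))


@pytest.fixture(scope="session")
def tiny_items():
    return [
        rc.ItemParams(-1.5, {0: 3.0}),
        rc.ItemParams(-1.2, {1: 2.5}),
        rc.ItemParams(-2.0, {0: 1.2, 1: 1.2}, {(0, 1): 1.8}),
    ]
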