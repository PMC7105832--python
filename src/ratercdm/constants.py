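"""Canonical simulation-study conditions.

The parameter-recovery studies shipped with this package use a fixed
benchmark condition: a 10-item, 5-attribute test judged by a pool of 10
raters, with known generating item parameters and rater severities, and a
set of four rating designs (complete, balanced incomplete, unbalanced
incomplete, random with fully-crossed anchor ratees).  A second,
checklist-style condition mirrors a realistic essay-marking application:
287 ratees × 52 binary checklist criteria × 9 raters with 1–2 raters per
essay.  Everything needed to regenerate those conditions lives here.
"""

from __future__ import annotations

import numpy as np

from .lcdm import ItemParams
from .qmatrix import QMatrix

# 10 items × 5 attributes: five simple-structure items then five two-attribute items.
STUDY_QMATRIX = QMatrix(np.array([
    [1, 0, 0, 0, 0],
    [0, 1, 0, 0, 0],
    [0, 0, 1, 0, 0],
    [0, 0, 0, 1, 0],
    [0, 0, 0, 0, 1],
    [1, 1, 0, 0, 0],
    [0, 1, 1, 0, 0],
    [0, 0, 1, 1, 0],
    [0, 0, 0, 1, 1],
    [1, 0, 0, 0, 1],
]))

_INTERCEPTS = [-2.00, -1.40, -1.79, -1.37, -1.85, -2.42, -1.57, -1.95, -2.07, -1.69]
_MAIN_EFFECTS = [3.72, 2.82, 3.41, 2.91, 3.38, 1.26, 1.04, 1.18, 1.00, 0.96]
_INTERACTIONS = [2.16, 2.14, 1.98, 2.05, 2.12]  # items 6-10

# Generating severities for the 10-rater pool; they sum to zero by construction.
STUDY_RATER_SEVERITIES = np.array(
    [0.57, 0.59, 0.70, 1.83, -0.50, -0.56, -0.10, -1.05, 0.55, -2.03])

# Inter-attribute correlation of the latent abilities behind the profiles.
STUDY_RHO = 0.5
STUDY_N_RATEES = 500


def study_item_params() -> list[ItemParams]:
    """Generating item parameters of the benchmark condition.

    Two-attribute items carry the listed main effect on *each* required
    attribute plus a two-way interaction; this is the reading under which
    the implied guessing range is [0.08, 0.20] and slip range [0.07, 0.19].
    """
    params: list[ItemParams] = []
    for j in range(10):
        required = tuple(np.flatnonzero(STUDY_QMATRIX.row(j)))
        mains = {k: _MAIN_EFFECTS[j] for k in required}
        inter = {required: _INTERACTIONS[j - 5]} if len(required) == 2 else {}
        params.append(ItemParams(_INTERCEPTS[j], mains, inter))
    return params


# Incomplete designs: 10 blocks of ratees, block b judged by a rotating
# triple of raters (0-based).  Block sizes distinguish the balanced and
# unbalanced layouts; the balanced layout gives every rater 150 ratees and
# the unbalanced layout the column totals (139, 167, 162, 170, 137, 144,
# 136, 156, 145, 144).
BLOCK_RATER_TRIPLES = [
    (0, 1, 2), (1, 2, 3), (2, 3, 4), (3, 4, 5), (4, 5, 6),
    (5, 6, 7), (6, 7, 8), (7, 8, 9), (8, 9, 0), (9, 0, 1),
]
BALANCED_BLOCK_SIZES = [50] * 10
UNBALANCED_BLOCK_SIZES = [50, 68, 44, 58, 35, 51, 50, 55, 40, 49]
UNBALANCED_COLUMN_TOTALS = [139, 167, 162, 170, 137, 144, 136, 156, 145, 144]

# Random design: a small fully-crossed anchor set links the rater pool.
RANDOM_DESIGN_ANCHORS = 20
INCOMPLETE_RATERS_PER_RATEE = 3

# HRM benchmark rating stage: all raters unbiased with moderate variability.
HRM_STUDY_PHI = 0.0
HRM_STUDY_PSI = 0.5

# ---------------------------------------------------------------------------
# Checklist-style condition (essay marking): 52 criteria × 6 attributes
# (content, organization, grammar, vocabulary, academic conventions,
# mechanics), 9 raters, each essay read by 1-2 of them.

CHECKLIST_ATTRIBUTES = (
    "content", "organization", "grammar", "vocabulary", "conventions", "mechanics")

CHECKLIST_QMATRIX = QMatrix(np.array([
    [1, 1, 1, 1, 1, 0],  # 1
    [1, 0, 0, 0, 0, 0],  # 2
    [1, 0, 0, 0, 0, 0],  # 3
    [0, 1, 1, 1, 0, 0],  # 4
    [0, 1, 1, 1, 0, 0],  # 5
    [1, 0, 1, 1, 1, 0],  # 6
    [1, 1, 1, 1, 0, 0],  # 7
    [1, 1, 0, 0, 0, 0],  # 8
    [1, 1, 0, 0, 0, 0],  # 9
    [1, 1, 0, 0, 0, 0],  # 10
    [1, 0, 0, 1, 0, 0],  # 11
    [1, 1, 0, 1, 0, 0],  # 12
    [1, 0, 0, 0, 0, 0],  # 13
    [0, 1, 0, 0, 1, 0],  # 14
    [0, 1, 0, 0, 0, 0],  # 15
    [0, 1, 0, 0, 0, 0],  # 16
    [0, 1, 0, 0, 0, 0],  # 17
    [0, 1, 0, 0, 0, 0],  # 18
    [0, 1, 0, 0, 0, 0],  # 19
    [0, 1, 0, 0, 0, 0],  # 20
    [0, 1, 1, 1, 0, 0],  # 21
    [0, 1, 1, 1, 0, 0],  # 22
    [0, 1, 1, 1, 0, 0],  # 23
    [0, 1, 1, 1, 0, 0],  # 24
    [0, 1, 0, 0, 0, 0],  # 25
    [0, 0, 1, 0, 0, 0],  # 26
    [0, 0, 1, 0, 0, 0],  # 27
    [0, 0, 1, 0, 0, 0],  # 28
    [0, 0, 1, 0, 0, 0],  # 29
    [0, 0, 1, 0, 0, 0],  # 30
    [0, 0, 1, 0, 0, 1],  # 31
    [0, 0, 1, 0, 0, 1],  # 32
    [0, 0, 1, 0, 0, 0],  # 33
    [0, 0, 1, 0, 0, 0],  # 34
    [0, 0, 1, 0, 0, 0],  # 35
    [0, 0, 1, 1, 0, 0],  # 36
    [0, 0, 1, 0, 0, 0],  # 37
    [0, 0, 1, 0, 0, 0],  # 38
    [0, 0, 1, 1, 0, 0],  # 39
    [0, 0, 1, 1, 0, 0],  # 40
    [0, 0, 0, 1, 0, 0],  # 41
    [0, 0, 0, 1, 0, 0],  # 42
    [0, 0, 0, 1, 0, 0],  # 43
    [0, 0, 0, 1, 0, 0],  # 44
    [0, 0, 1, 1, 0, 0],  # 45
    [0, 0, 0, 1, 0, 1],  # 46
    [0, 0, 0, 1, 0, 1],  # 47
    [0, 0, 1, 0, 0, 1],  # 48
    [0, 0, 0, 0, 0, 1],  # 49
    [0, 0, 0, 0, 0, 1],  # 50
    [0, 0, 1, 1, 1, 0],  # 51
    [0, 0, 1, 1, 1, 0],  # 52
]), CHECKLIST_ATTRIBUTES)

CHECKLIST_N_RATEES = 287
CHECKLIST_N_RATERS = 9

# Rating-stage parameters of the 9-rater checklist pool: two notably severe
# raters (1 and 7), variabilities from tight (0.37) to loose (1.28).
CHECKLIST_RATER_PHI = np.array([0.40, 0.02, 0.01, 0.02, 0.01, 0.02, 0.24, 0.04, 0.02])
CHECKLIST_RATER_PSI = np.array([0.37, 0.84, 0.69, 0.70, 0.53, 0.52, 0.76, 1.28, 0.49])
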