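"""Reference presets for the 11-item volcano-science simulation task.

The study task has seven selected-response knowledge items (Items 1-7)
followed by four constructed-response items around a seismometer
simulation (Item 8 is the simulation itself; Items 9-11 ask the test
taker to explain the design).  Chance-level proportions correct follow
from the response formats: 1/4 for the 4-option single-selection items,
1/3 for the multiple-selection item (2 of 3 options), 1/5! = 1/120 for
the 5-option ordering item, and 0 for the CR items.

``ITEM_PARAMS`` carries published EAP estimates of the joint-model item
parameters (time-intensity beta on the log-seconds scale,
time-discrimination alpha, Rasch difficulty b) used as the generating
values of the "study-like" synthetic preset, together with the Level-2
person covariance (variances of ability and speed plus their
covariance).
"""

from __future__ import annotations

import math

import numpy as np

from .data_model import ItemMeta

__all__ = ["STUDY_ITEMS", "ITEM_PARAMS", "PERSON_COV", "study_items"]

# (item_type, response_format, chance_pc)
_ITEM_TABLE = [
    ("MC", "single-selection", 0.25),
    ("MC", "single-selection", 0.25),
    ("MC", "multiple-selection", 1.0 / 3.0),
    ("MC", "order", 1.0 / math.factorial(5)),
    ("MC", "single-selection", 0.25),
    ("MC", "single-selection", 0.25),
    ("MC", "single-selection", 0.25),
    ("CR", "simulation", 0.0),
    ("CR", "explanation", 0.0),
    ("CR", "explanation", 0.0),
    ("CR", "explanation", 0.0),
]

STUDY_ITEMS: list[ItemMeta] = [
    ItemMeta(item_id=i + 1, item_type=t, response_format=f, chance_pc=c)
    for i, (t, f, c) in enumerate(_ITEM_TABLE)
]


def study_items() -> list[ItemMeta]:
    """A fresh copy of the 11-item metadata list."""
    return list(STUDY_ITEMS)


# EAP item-parameter estimates used as generating truth in the
# study-like synthetic preset.
ITEM_PARAMS = {
    "beta": np.array(
        [3.06, 2.60, 2.59, 3.49, 2.81, 2.96, 1.94, 3.76, 3.27, 2.31, 3.31]
    ),
    "alpha": np.array(
        [4.02, 5.12, 3.68, 7.58, 6.28, 5.59, 7.45, 3.80, 2.65, 10.03, 3.16]
    ),
    "b": np.array(
        [-0.72, -0.58, -0.93, -0.43, -3.07, -2.05, -3.90, -2.94, -0.32, -0.18, 1.30]
    ),
}

# Level-2 moments: person (ability, speed) covariance entries and the
# item (difficulty, time-intensity) mean/covariance.
PERSON_COV = {"sigma_theta2": 0.85, "sigma_thetatau": 0.04, "sigma_tau2": 0.08}
ITEM_COV = {"sigma_b2": 2.77, "sigma_bbeta": 0.24, "sigma_beta2": 0.43}
ITEM_MEAN = {"mu_b": float(ITEM_PARAMS["b"].mean()), "mu_beta": float(ITEM_PARAMS["beta"].mean())}
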