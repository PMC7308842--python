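"""Bundled reference confusion matrix for the 13-activity DaLiAc benchmark.

This is the published aggregated confusion matrix of the all-device
logistic-regression hierarchy over 19 leave-one-subject-out rounds on the
DaLiAc dataset (rows = true class, columns = predicted class). It ships with
the package so per-class precision/recall/f-score arithmetic can be
exercised and demonstrated without downloading the dataset.
"""

from __future__ import annotations

import numpy as np

from .evaluation import ConfusionMatrix
from .hierarchy import DALIAC_ACTIVITIES

__all__ = ["daliac_reference_confusion"]

_MATRIX = np.array([
    #  sit  lie  stnd wash  vac  swp  walk  s-up s-dn  run  b50  b100 jump
    [430,   0,  17,   3,   0,   0,    0,   0,   0,   0,   0,   0,   0],  # sit
    [  1, 455,   0,   0,   0,   0,    0,   0,   0,   0,   0,   0,   0],  # lie
    [  2,   0, 442,   8,   0,   0,    1,   0,   0,   0,   0,   0,   0],  # stand
    [  0,   0,   2, 924,   7,   4,    0,   0,   0,   0,   0,   0,   0],  # wash
    [  0,   0,   0,   7, 422,  25,    0,   0,   0,   0,   0,   0,   0],  # vacuum
    [  0,   0,   6,   4,  23, 704,    4,   2,   0,   0,   0,   0,   0],  # sweep
    [  0,   0,   3,   1,   4,   5, 2010,  11,   6,   1,   0,   0,   0],  # walk
    [  0,   0,   0,   0,   0,   1,    6, 312,   1,   0,   0,   0,   0],  # stairs_up
    [  0,   0,   0,   0,   0,   0,    5,   2, 266,   0,   0,   0,   0],  # stairs_down
    [  0,   0,   0,   0,   0,   0,    0,   0,   0, 910,   1,   0,   0],  # run
    [  0,   0,   0,   0,   0,   0,    0,   0,   0,   0, 877,  46,   0],  # bike_50w
    [  0,   0,   0,   0,   0,   0,    0,   0,   0,   0,  37, 883,   2],  # bike_100w
    [  0,   0,   0,   0,   0,   0,    0,   0,   0,   0,   0,   0, 243],  # jump
], dtype=int)


def daliac_reference_confusion() -> ConfusionMatrix:
    """The bundled 13x13 aggregated LOSO confusion matrix (9126 windows)."""
    return ConfusionMatrix(counts=_MATRIX.copy(), classes=list(DALIAC_ACTIVITIES))
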