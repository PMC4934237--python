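"""Reference data: published confusion matrices of the five-sensor glove study.

The validation experiment behind the optimally designed five-sensor glove
had five subjects perform eight functional grasp types, three repetitions
each (120 trials).  Leave-one-subject-out recognition produced one 8 x 8
confusion matrix per held-out subject (rows = true grasp type, columns =
recognized cluster; each row sums to 12 = 4 remaining subjects x 3
repetitions).  The full count matrices were published and are reproduced
here verbatim so that the accuracy figures can be recomputed from counts.
"""

from __future__ import annotations

import numpy as np

from .recognition import ConfusionMatrix


def _cm(rows) -> ConfusionMatrix:
    return ConfusionMatrix(counts=np.array(rows, dtype=int))


#: One confusion matrix per held-out subject (1..5), in subject order.
REFERENCE_CONFUSIONS: tuple[ConfusionMatrix, ...] = (
    # subject 1: perfect recognition
    _cm(12 * np.eye(8, dtype=int)),
    # subject 2: perfect recognition
    _cm(12 * np.eye(8, dtype=int)),
    # subject 3: grasp 2 partly confused with grasp 6, 3 with 1, 6 with 4
    _cm([
        [12, 0, 0, 0, 0, 0, 0, 0],
        [0, 10, 0, 0, 0, 2, 0, 0],
        [1, 0, 11, 0, 0, 0, 0, 0],
        [0, 0, 0, 12, 0, 0, 0, 0],
        [0, 0, 0, 0, 12, 0, 0, 0],
        [0, 0, 0, 1, 0, 11, 0, 0],
        [0, 0, 0, 0, 0, 0, 12, 0],
        [0, 0, 0, 0, 0, 0, 0, 12],
    ]),
    # subject 4: grasp 2 confused with 6 three times, 6 with 4 once
    _cm([
        [12, 0, 0, 0, 0, 0, 0, 0],
        [0, 9, 0, 0, 0, 3, 0, 0],
        [0, 0, 12, 0, 0, 0, 0, 0],
        [0, 0, 0, 12, 0, 0, 0, 0],
        [0, 0, 0, 0, 12, 0, 0, 0],
        [0, 0, 0, 1, 0, 11, 0, 0],
        [0, 0, 0, 0, 0, 0, 12, 0],
        [0, 0, 0, 0, 0, 0, 0, 12],
    ]),
    # subject 5: a single grasp 2 -> 6 confusion
    _cm([
        [12, 0, 0, 0, 0, 0, 0, 0],
        [0, 11, 0, 0, 0, 1, 0, 0],
        [0, 0, 12, 0, 0, 0, 0, 0],
        [0, 0, 0, 12, 0, 0, 0, 0],
        [0, 0, 0, 0, 12, 0, 0, 0],
        [0, 0, 0, 0, 0, 12, 0, 0],
        [0, 0, 0, 0, 0, 0, 12, 0],
        [0, 0, 0, 0, 0, 0, 0, 12],
    ]),
)
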