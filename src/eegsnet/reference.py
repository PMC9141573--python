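"""Published benchmark confusion matrices for the EEGSNet architecture.

The original cross-validation results on the four public polysomnography
benchmarks — Sleep-EDFX-8, Sleep-EDFX-20, Sleep-EDFX-78 and SHHS — were
reported as 5×5 confusion matrices (rows = reference scoring by specialists,
columns = model prediction, class order W/N1/N2/N3/REM).  They are bundled
here so the metrics suite can be exercised, and its published headline
numbers reproduced, without downloading any data.
"""

from __future__ import annotations

import numpy as np

__all__ = ["REFERENCE_CONFUSIONS"]

REFERENCE_CONFUSIONS: dict[str, np.ndarray] = {
    "sleep-edfx-8": np.array(
        [
            [7873, 46, 13, 7, 6],
            [50, 388, 105, 4, 52],
            [8, 49, 3230, 234, 55],
            [3, 0, 104, 1191, 1],
            [14, 24, 96, 3, 1444],
        ],
        dtype=np.int64,
    ),
    "sleep-edfx-20": np.array(
        [
            [7585, 291, 102, 20, 88],
            [363, 1291, 673, 12, 429],
            [336, 382, 15596, 741, 554],
            [29, 1, 663, 4914, 2],
            [133, 194, 491, 0, 6860],
        ],
        dtype=np.int64,
    ),
    "sleep-edfx-78": np.array(
        [
            [61212, 3406, 506, 44, 462],
            [3359, 9744, 6568, 133, 1683],
            [539, 3097, 58825, 4259, 2276],
            [20, 22, 2580, 10360, 8],
            [608, 1199, 2263, 59, 21618],
        ],
        dtype=np.int64,
    ),
    "shhs": np.array(
        [
            [41458, 1222, 2261, 260, 900],
            [1706, 4221, 2857, 24, 1460],
            [2397, 1534, 120994, 11945, 4725],
            [409, 2, 8896, 50471, 230],
            [1562, 615, 4824, 346, 58481],
        ],
        dtype=np.int64,
    ),
}
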