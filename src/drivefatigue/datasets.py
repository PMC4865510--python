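"""Published per-subject summary statistics for the eleven drivers.

The original study deposited no raw recordings; what is public are the
per-subject summary tables — mean heart rate and session Driving
Condition Level under the two driving conditions.  They are included
here so the index arithmetic (rDCL, outlier counts, condition means) can
be exercised against published numbers.
"""

from __future__ import annotations

import numpy as np

SUBJECTS = tuple(f"S{i}" for i in range(1, 12))

#: Mean heart rate (beats/min) per subject over the 30-min drive.
HR_WELL_RESTED = np.array(
    [71.6, 65.3, 78.5, 76.2, 71.0, 68.2, 68.1, 76.8, 66.7, 65.7, 60.9])
HR_SLEEP_DEPRIVED = np.array(
    [62.0, 58.2, 61.3, 55.7, 62.3, 64.2, 63.0, 67.3, 64.2, 62.4, 59.2])

#: Session-level Driving Condition Level per subject (0-3 scale).
DCL_WELL_RESTED = np.array(
    [2.52, 2.48, 2.31, 2.04, 2.24, 2.75, 1.94, 2.80, 1.94, 2.01, 2.00])
DCL_SLEEP_DEPRIVED = np.array(
    [1.47, 1.17, 1.44, 1.07, 1.11, 1.73, 1.42, 1.88, 1.54, 1.19, 1.21])
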