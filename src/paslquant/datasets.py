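"""Bundled reference data.

``cerebellum_cbf_table`` returns published per-subject cerebellar CBF
values (mL/100 g/min) from a five-subject comparison of two pulsed-ASL
labeling schemes — FAIR with additional superior saturation (FAIR ASST) and
PICORE — measured at TI1/TI2 = 800/1800 ms.  The per-subject grey- and
white-matter values are the primary data; all group rows (mean, S.D.,
C.V.%, GM/WM ratios) are derived quantities that
:func:`paslquant.roi_analysis.perfusion_report` recomputes.
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # subject, method, cbf_gm, cbf_wm
    (1, "FAIR_ASST", 42.58, 29.56),
    (2, "FAIR_ASST", 45.07, 28.63),
    (3, "FAIR_ASST", 37.89, 20.48),
    (4, "FAIR_ASST", 41.82, 26.62),
    (5, "FAIR_ASST", 51.57, 32.53),
    (1, "PICORE", 41.97, 33.50),
    (2, "PICORE", 44.47, 28.89),
    (3, "PICORE", 30.28, 19.04),
    (4, "PICORE", 33.59, 14.71),
    (5, "PICORE", 51.45, 22.51),
]


def cerebellum_cbf_table() -> pd.DataFrame:
    """Per-subject cerebellar GM/WM CBF for two pulsed-ASL methods."""
    return pd.DataFrame(_ROWS,
                        columns=["subject", "method", "cbf_gm", "cbf_wm"])
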