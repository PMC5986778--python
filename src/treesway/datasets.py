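"""Reference measurement values for a pull-and-release tree-sway test.

The values below are the published per-marker results of a pull-and-release
experiment on a de-branched, pole-like horse-chestnut stem (1540 mm tall,
31.5 mm basal diameter) whose vibrations were recorded with an infrared
motion-capture system.  Three markers along the trunk were analysed with
the orthogonal-oscillation procedure implemented by this package; the raw
recordings are not available, so these fitted parameters are the reference
against which derived quantities (vibration frequencies in Hz, damping
factors, column means) can be recomputed.

Columns: coincidence time ``t1`` (s), principal-axis angle ``alpha``
(degrees), natural frequencies ``omega1 <= omega2`` (rad/s) and decay
constants ``delta1, delta2`` (1/s) for the two principal axes.
"""

from __future__ import annotations

import math

import pandas as pd

__all__ = ["reference_marker_table", "reference_summary"]

_ROWS = [
    # marker, t1_s, alpha_deg, omega1, omega2, delta1, delta2
    (1, 7.086, 52.524, 21.557, 21.839, 0.517, 0.652),
    (2, 7.115, 52.954, 21.563, 21.858, 0.525, 0.654),
    (3, 7.126, 52.376, 21.564, 21.862, 0.518, 0.642),
]


def reference_marker_table() -> pd.DataFrame:
    """Per-marker reference parameters as a DataFrame indexed by marker."""
    df = pd.DataFrame(
        _ROWS,
        columns=[
            "marker",
            "t1_s",
            "alpha_deg",
            "omega1_rad_per_s",
            "omega2_rad_per_s",
            "delta1_per_s",
            "delta2_per_s",
        ],
    )
    return df.set_index("marker")


def reference_summary() -> dict:
    """Across-marker summary and the derived quantities.

    Column means are quoted at the customary precision (one decimal for
    omega1, two for omega2 and the deltas); the vibration frequencies
    ``f = omega/(2*pi)`` in Hz and damping factors ``zeta = delta/omega``
    are then derived from those quoted values, mirroring how such summaries
    are reported.
    """
    df = reference_marker_table()
    omega1 = round(df["omega1_rad_per_s"].mean(), 1)
    omega2 = round(df["omega2_rad_per_s"].mean(), 2)
    delta1 = round(df["delta1_per_s"].mean(), 2)
    delta2 = round(df["delta2_per_s"].mean(), 2)
    return {
        "omega1_rad_per_s": omega1,
        "omega2_rad_per_s": omega2,
        "delta1_per_s": delta1,
        "delta2_per_s": delta2,
        "f1_hz": omega1 / (2 * math.pi),
        "f2_hz": omega2 / (2 * math.pi),
        "zeta1": delta1 / omega1,
        "zeta2": delta2 / omega2,
        "alpha_deg_mean": float(df["alpha_deg"].mean()),
        "t1_s_mean": float(df["t1_s"].mean()),
    }
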