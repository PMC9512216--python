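"""Published reference summary values for the six recorder/speaking tasks.

A previously published study of vapor-cloud dispersion while playing the
soprano recorder reports, for six tasks (T1 speaking, T2 low octave, T3 high
octave, T4 mask + bell-hole tissue, T5 paper towel, T6 suction funnel), the
median and maximum frontal (x) and lateral-diameter (y) extents across five
subjects at 0, 3 and 10 s after task end, with each cell of T2-T3 marked
against T1 and each cell of T4-T6 marked against T3 using an inclusive
+/-0.1 m rule.  These printed values are bundled as the worked-example
dataset for the comparison-markup classifier and the difference reports.
"""

from __future__ import annotations

from typing import Dict, Tuple

import pandas as pd

from .summary import SummaryTable

__all__ = ["load_reference_summary", "load_reference_marks", "reference_mark_frame"]

# (task, dimension, statistic) -> (value at 0 s, 3 s, 10 s) in metres
_VALUES = {
    ("T1", "x_front", "median"): (0.83, 1.12, 1.41),
    ("T1", "x_front", "maximum"): (1.32, 1.89, 2.58),
    ("T1", "y_diameter", "median"): (0.84, 0.97, 0.58),
    ("T1", "y_diameter", "maximum"): (1.16, 1.43, 1.62),
    ("T2", "x_front", "median"): (0.97, 0.90, 0.97),
    ("T2", "x_front", "maximum"): (1.38, 1.44, 1.50),
    ("T2", "y_diameter", "median"): (0.47, 0.42, 0.04),
    ("T2", "y_diameter", "maximum"): (0.77, 1.00, 1.14),
    ("T3", "x_front", "median"): (1.06, 0.93, 1.01),
    ("T3", "x_front", "maximum"): (1.35, 1.62, 2.17),
    ("T3", "y_diameter", "median"): (0.57, 0.53, 0.23),
    ("T3", "y_diameter", "maximum"): (0.97, 0.83, 0.72),
    ("T4", "x_front", "median"): (0.65, 0.81, 0.70),
    ("T4", "x_front", "maximum"): (1.40, 1.74, 2.28),
    ("T4", "y_diameter", "median"): (0.56, 0.67, 0.65),
    ("T4", "y_diameter", "maximum"): (0.78, 0.77, 0.81),
    ("T5", "x_front", "median"): (1.17, 1.28, 1.36),
    ("T5", "x_front", "maximum"): (1.31, 1.51, 1.93),
    ("T5", "y_diameter", "median"): (0.59, 0.70, 0.70),
    ("T5", "y_diameter", "maximum"): (0.74, 0.96, 1.29),
    ("T6", "x_front", "median"): (0.65, 0.42, 0.39),
    ("T6", "x_front", "maximum"): (1.16, 1.14, 1.46),
    ("T6", "y_diameter", "median"): (0.19, 0.08, 0.08),
    ("T6", "y_diameter", "maximum"): (0.65, 0.55, 0.62),
}

# Printed typography of the marked tasks: italic = HIGHER than the reference,
# bold = LOWER, plain = COMPARABLE.  H/L/C per (0 s, 3 s, 10 s).
_MARKS = {
    ("T2", "x_front", "median"): "HLL",
    ("T2", "x_front", "maximum"): "CLL",
    ("T2", "y_diameter", "median"): "LLL",
    ("T2", "y_diameter", "maximum"): "LLL",
    ("T3", "x_front", "median"): "HLL",
    ("T3", "x_front", "maximum"): "CLL",
    ("T3", "y_diameter", "median"): "LLL",
    ("T3", "y_diameter", "maximum"): "LLL",
    ("T4", "x_front", "median"): "LLL",
    ("T4", "x_front", "maximum"): "CHH",
    ("T4", "y_diameter", "median"): "CHH",
    ("T4", "y_diameter", "maximum"): "LCC",
    ("T5", "x_front", "median"): "HHH",
    ("T5", "x_front", "maximum"): "CLL",
    ("T5", "y_diameter", "median"): "CHH",
    ("T5", "y_diameter", "maximum"): "LHH",
    ("T6", "x_front", "median"): "LLL",
    ("T6", "x_front", "maximum"): "LLL",
    ("T6", "y_diameter", "median"): "LLL",
    ("T6", "y_diameter", "maximum"): "LLL",
}

_TIMEPOINTS = (0.0, 3.0, 10.0)
_MARK_NAMES = {"H": "HIGHER", "L": "LOWER", "C": "COMPARABLE"}


def load_reference_summary() -> SummaryTable:
    """The published summary values as a SummaryTable (72 cells)."""
    records = [
        dict(task=task, dimension=dim, statistic=stat, timepoint_s=tp, value_m=v)
        for (task, dim, stat), values in _VALUES.items()
        for tp, v in zip(_TIMEPOINTS, values)
    ]
    return SummaryTable(records)


def load_reference_marks() -> Dict[Tuple[str, str, str, float], str]:
    """Printed comparison marks for the 60 marked cells (T2-T6)."""
    return {
        (task, dim, stat, tp): _MARK_NAMES[code]
        for (task, dim, stat), codes in _MARKS.items()
        for tp, code in zip(_TIMEPOINTS, codes)
    }


def reference_mark_frame() -> pd.DataFrame:
    """Printed marks as a tidy DataFrame."""
    rows = [
        dict(task=t, dimension=d, statistic=s, timepoint_s=tp, printed_mark=m)
        for (t, d, s, tp), m in load_reference_marks().items()
    ]
    return pd.DataFrame(rows)
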