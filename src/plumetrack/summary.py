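"""Cross-subject summaries, median curves and the +/-0.1 m comparison markup.

The summary table holds, per task and dimension, the median and maximum over
subjects of the smoothed extent at fixed time points after the task end
(default 0, 3 and 10 s).  Frontal x and lateral y-diameter values form the
main table; vertical z statistics are computed but kept separately.  Each
non-reference task is compared cell-by-cell against its reference task and
classified HIGHER / LOWER / COMPARABLE with an inclusive +/-0.1 m tolerance
on values rounded to 0.01 m.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .geometry import DIRECTIONS, ExtentSeries

__all__ = [
    "ComparisonMark",
    "SummaryTable",
    "summarize",
    "median_curve",
    "classify_vs_reference",
    "mark_table",
    "report_differences",
    "REFERENCE_TASK",
]

#: which task each marked task is compared against
REFERENCE_TASK = {"T2": "T1", "T3": "T1", "T4": "T3", "T5": "T3", "T6": "T3"}

TABLE_DIMENSIONS = ("x_front", "y_diameter")
Z_DIMENSIONS = ("z_up", "z_down")
STATISTICS = ("median", "maximum")

Cell = Tuple[str, str, str, float]  # (task, dimension, statistic, timepoint_s)


@dataclass(frozen=True)
class ComparisonMark:
    """Outcome of comparing one summary cell against its reference task."""

    mark: str  # HIGHER | LOWER | COMPARABLE
    difference_m: float
    tolerance_m: float = 0.1


def classify_vs_reference(
    value_m: float, reference_m: float, tolerance_m: float = 0.1
) -> ComparisonMark:
    """Classify a value against a reference with an inclusive tolerance.

    Values are rounded to 0.01 m (printed precision) before comparison;
    |difference| >= tolerance yields HIGHER/LOWER, otherwise COMPARABLE.
    """
    if tolerance_m < 0:
        raise ValueError(f"tolerance must be >= 0, got {tolerance_m}")
    if value_m < 0 or reference_m < 0:
        raise ValueError("extent values must be >= 0")
    diff = round(round(float(value_m), 2) - round(float(reference_m), 2), 2)
    if diff >= tolerance_m - 1e-9:
        mark = "HIGHER"
    elif -diff >= tolerance_m - 1e-9:
        mark = "LOWER"
    else:
        mark = "COMPARABLE"
    return ComparisonMark(mark=mark, difference_m=diff, tolerance_m=tolerance_m)


class SummaryTable:
    """Per task x dimension x statistic x timepoint summary values in metres."""

    def __init__(self, records: Sequence[dict]):
        df = pd.DataFrame.from_records(
            records, columns=["task", "dimension", "statistic", "timepoint_s", "value_m"]
        )
        if df.duplicated(["task", "dimension", "statistic", "timepoint_s"]).any():
            raise ValueError("duplicate summary cells")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def tasks(self) -> List[str]:
        return sorted(self.df["task"].unique())

    def value(self, task: str, dimension: str, statistic: str, timepoint_s: float) -> float:
        sel = self.df[
            (self.df["task"] == task)
            & (self.df["dimension"] == dimension)
            & (self.df["statistic"] == statistic)
            & (np.isclose(self.df["timepoint_s"], timepoint_s))
        ]
        if sel.empty:
            raise KeyError(
                f"no summary cell ({task}, {dimension}, {statistic}, {timepoint_s} s)"
            )
        return float(sel["value_m"].iloc[0])

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SummaryTable":
        return cls(pd.read_csv(path).to_dict("records"))


def _timepoint_value(series: ExtentSeries, direction: str, t: float) -> Optional[float]:
    if getattr(series, direction) is None:
        return None
    return series.value_at(direction, t)


def summarize(
    series: Sequence[ExtentSeries],
    timepoints_s: Sequence[float] = (0.0, 3.0, 10.0),
) -> Tuple[SummaryTable, SummaryTable]:
    """Median and maximum across subjects at each timepoint, per task.

    Timepoint lookup is the nearest time-grid sample (within half a frame).
    Returns ``(table, z_table)``: the main x/y table and the separately kept
    vertical z statistics.
    """
    if not series:
        raise ValueError("need at least one series")
    by_task: Dict[str, List[ExtentSeries]] = {}
    for s in series:
        by_task.setdefault(s.task_id, []).append(s)

    main_records, z_records = [], []
    for task in sorted(by_task):
        members = by_task[task]
        for dimension in DIRECTIONS:
            values_by_tp = {}
            for t in timepoints_s:
                vals = [
                    v
                    for v in (_timepoint_value(s, dimension, t) for s in members)
                    if v is not None
                ]
                if vals:
                    values_by_tp[t] = vals
            target = main_records if dimension in TABLE_DIMENSIONS else z_records
            for t, vals in values_by_tp.items():
                target.append(
                    dict(
                        task=task,
                        dimension=dimension,
                        statistic="median",
                        timepoint_s=float(t),
                        value_m=float(np.median(vals)),
                    )
                )
                target.append(
                    dict(
                        task=task,
                        dimension=dimension,
                        statistic="maximum",
                        timepoint_s=float(t),
                        value_m=float(np.max(vals)),
                    )
                )
    return SummaryTable(main_records), SummaryTable(z_records)


def median_curve(series: Sequence[ExtentSeries]) -> pd.DataFrame:
    """Pointwise median across subjects per direction on the common time range."""
    if not series:
        raise ValueError("need at least one series")
    fps = series[0].fps
    if any(s.fps != fps for s in series):
        raise ValueError("all series must share the same fps")
    t0 = max(s.time_s[0] for s in series)
    t1 = min(s.time_s[-1] for s in series)
    if t1 < t0 - 1e-9:
        raise ValueError("series have no overlapping time range")
    n = int(round((t1 - t0) * fps)) + 1
    time = t0 + np.arange(n) / fps
    out = {"time_s": time}
    for d in DIRECTIONS:
        stacks = []
        for s in series:
            arr = getattr(s, d)
            if arr is None:
                continue
            k0 = int(round((t0 - s.time_s[0]) * fps))
            stacks.append(arr[k0 : k0 + n])
        if stacks:
            out[f"{d}_m"] = np.median(np.vstack(stacks), axis=0)
    return pd.DataFrame(out)


def mark_table(
    table: SummaryTable,
    reference_task: Optional[Dict[str, str]] = None,
    tolerance_m: float = 0.1,
) -> pd.DataFrame:
    """Classify every cell of the marked tasks against its reference task."""
    scheme = REFERENCE_TASK if reference_task is None else reference_task
    tasks_present = set(table.df["task"])
    rows = []
    for _, row in table.df.iterrows():
        ref_task = scheme.get(row["task"])
        if ref_task is None or ref_task not in tasks_present:
            continue
        ref_value = table.value(
            ref_task, row["dimension"], row["statistic"], row["timepoint_s"]
        )
        mark = classify_vs_reference(row["value_m"], ref_value, tolerance_m)
        rows.append(
            dict(
                task=row["task"],
                dimension=row["dimension"],
                statistic=row["statistic"],
                timepoint_s=row["timepoint_s"],
                value_m=row["value_m"],
                reference_task=ref_task,
                reference_m=ref_value,
                difference_m=mark.difference_m,
                mark=mark.mark,
            )
        )
    return pd.DataFrame(rows)


def report_differences(
    table: SummaryTable, pairs: Sequence[Tuple[Cell, Cell]]
) -> List[float]:
    """Cell-wise differences (cellA - cellB) in metres at 0.01 m precision."""
    out = []
    for cell_a, cell_b in pairs:
        a = table.value(*cell_a)
        b = table.value(*cell_b)
        out.append(round(round(a, 2) - round(b, 2), 2))
    return out
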