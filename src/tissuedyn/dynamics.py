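"""Time-course assembly and transient-vs-sustained dynamics classification.

After genotoxic stress, some tissues (small and large intestine) show a
signal pulse that peaks around 2 h and returns close to baseline by 5 h,
while others (spleen, thymus) stay elevated through at least 7 h.  The
classifier operationalizes that contrast with one scale-free number: the
late-to-peak ratio r = (value(late) - baseline) / (peak - baseline),
transient when r < threshold, sustained otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

TRANSIENT = "transient"
SUSTAINED = "sustained"
INDETERMINATE = "indeterminate"


@dataclass
class TimeCourse:
    """Ordered per-timepoint summaries for one tissue/treatment."""

    tissue: str
    treatment: str
    timepoints: np.ndarray  # strictly increasing, hours
    values: np.ndarray
    sems: np.ndarray
    n_cells: np.ndarray
    baseline: float
    dynamics_class: Optional[str] = None
    peak_time: Optional[float] = None
    late_to_peak_ratio: Optional[float] = None


def assemble_timecourse(
    summaries: pd.DataFrame,
    tissue: str,
    treatment: Optional[str] = None,
) -> TimeCourse:
    """Assemble a tissue's time course from a summary table.

    Expects columns tissue, treatment, time_h, summary (and optionally
    sem, n_cells).  Rows are sorted by time; duplicate
    (tissue, treatment, time) rows are an input error.  The baseline is
    the t = 0 value when present, else the series minimum.
    """
    rows = summaries[summaries["tissue"] == tissue]
    if treatment is not None:
        rows = rows[rows["treatment"] == treatment]
    if rows["time_h"].duplicated().any():
        dup = sorted(rows.loc[rows["time_h"].duplicated(), "time_h"].unique())
        raise ValueError(
            f"duplicate timepoints for ({tissue!r}, {treatment!r}): {dup}; "
            "summarize replicate samples before assembling"
        )
    if len(rows) < 2:
        raise ValueError(f"need >= 2 timepoints for {tissue!r}, got {len(rows)}")
    rows = rows.sort_values("time_h")
    t = rows["time_h"].to_numpy(dtype=float)
    v = rows["summary"].to_numpy(dtype=float)
    sems = (
        rows["sem"].to_numpy(dtype=float)
        if "sem" in rows.columns
        else np.zeros_like(v)
    )
    n_cells = (
        rows["n_cells"].to_numpy(dtype=int)
        if "n_cells" in rows.columns
        else np.zeros(len(v), dtype=int)
    )
    baseline = float(v[t == 0.0][0]) if (t == 0.0).any() else float(v.min())
    tr = treatment if treatment is not None else str(rows["treatment"].iloc[0])
    return TimeCourse(
        tissue=tissue,
        treatment=tr,
        timepoints=t,
        values=v,
        sems=sems,
        n_cells=n_cells,
        baseline=baseline,
    )


def classify_dynamics(
    tc: TimeCourse,
    late_time: float = 5.0,
    ratio_threshold: float = 0.5,
) -> str:
    """Classify a time course as transient, sustained, or indeterminate.

    r = (value(late_time) - baseline) / (peak - baseline); transient when
    r < ratio_threshold, sustained when r >= ratio_threshold,
    indeterminate when the series never rises above baseline.  r is
    invariant under affine rescaling of the whole series.  Updates and
    returns ``tc.dynamics_class``.
    """
    t, v = tc.timepoints, tc.values
    matches = np.flatnonzero(np.isclose(t, late_time))
    if matches.size == 0:
        raise ValueError(
            f"late_time {late_time} not among timepoints {t.tolist()}"
        )
    peak_idx = int(np.argmax(v))
    peak = float(v[peak_idx])
    tc.peak_time = float(t[peak_idx])
    if peak <= tc.baseline:
        tc.dynamics_class = INDETERMINATE
        tc.late_to_peak_ratio = None
        return INDETERMINATE
    r = (float(v[matches[0]]) - tc.baseline) / (peak - tc.baseline)
    tc.late_to_peak_ratio = max(r, 0.0)
    tc.dynamics_class = TRANSIENT if r < ratio_threshold else SUSTAINED
    return tc.dynamics_class


def intensity_histogram(
    values: np.ndarray, bin_edges: Sequence[float]
) -> Tuple[np.ndarray, int, int]:
    """Histogram with half-open [low, high) bins (last bin closed).

    Returns (counts, n_underflow, n_overflow); counts sum plus the two
    overflow tallies conserves the number of input cells.
    """
    edges = np.asarray(bin_edges, dtype=np.float64)
    if edges.size < 2:
        raise ValueError("need at least 2 bin edges")
    if not np.all(np.diff(edges) > 0):
        raise ValueError("bin_edges must be strictly increasing")
    values = np.asarray(values, dtype=np.float64).ravel()
    counts, _ = np.histogram(values, bins=edges)
    underflow = int(np.count_nonzero(values < edges[0]))
    overflow = int(np.count_nonzero(values > edges[-1]))
    return counts, underflow, overflow


def timecourse_table(timecourses: List[TimeCourse]) -> pd.DataFrame:
    """Flatten classified time courses into the output table format."""
    rows = []
    for tc in timecourses:
        for i in range(len(tc.timepoints)):
            rows.append(
                {
                    "tissue": tc.tissue,
                    "treatment": tc.treatment,
                    "time_h": tc.timepoints[i],
                    "summary": tc.values[i],
                    "sem": tc.sems[i],
                    "n_cells": tc.n_cells[i],
                    "dynamics_class": tc.dynamics_class,
                    "peak_time": tc.peak_time,
                    "late_to_peak_ratio": tc.late_to_peak_ratio,
                }
            )
    return pd.DataFrame(rows)
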