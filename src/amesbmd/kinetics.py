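"""CYP2E1 activity computations: metabolite-formation rate and percent of control.

The probe reaction is chlorzoxazone 6-hydroxylation by liver S9 fractions
measured over a 0-30 minute time course.  The formation rate is the
ordinary least-squares slope of mean metabolite concentration against
time; the intercept is estimated rather than forced through zero because
time-zero samples may carry background signal.  Vehicle effects are
expressed as metabolite formation relative to a water control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TimeCourse",
    "RateEstimate",
    "formation_rate",
    "percent_of_control",
    "read_timecourse_csv",
]

#: the study's sampling scheme, minutes
DEFAULT_TIMEPOINTS = (0.0, 2.0, 6.0, 12.0, 18.0, 30.0)


@dataclass(frozen=True)
class TimeCourse:
    """Metabolite amounts per timepoint, possibly with replicates.

    ``concentrations`` has shape (n_replicates, n_timepoints) or
    (n_timepoints,).
    """

    timepoints: tuple
    concentrations: tuple

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        if len(t) < 2:
            raise ValueError("need at least two timepoints")
        if t[0] != 0:
            raise ValueError("time course must start at 0 min")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        c = np.asarray(self.concentrations, dtype=float)
        if c.ndim == 1:
            c = c[None, :]
        if c.shape[1] != len(t):
            raise ValueError("concentrations must align with timepoints")
        object.__setattr__(self, "timepoints", tuple(t))
        object.__setattr__(self, "concentrations", tuple(map(tuple, c)))

    def mean_concentrations(self) -> np.ndarray:
        return np.asarray(self.concentrations, dtype=float).mean(axis=0)


@dataclass(frozen=True)
class RateEstimate:
    """Formation rate (amount/min) with its standard error and intercept."""

    rate: float
    stderr: float
    intercept: float


def formation_rate(tc: TimeCourse) -> RateEstimate:
    """OLS slope of mean metabolite concentration against time."""
    t = np.asarray(tc.timepoints)
    y = tc.mean_concentrations()
    res = stats.linregress(t, y)
    return RateEstimate(
        rate=float(res.slope),
        stderr=float(res.stderr),
        intercept=float(res.intercept),
    )


def percent_of_control(test_amount: float, control_amount: float) -> float:
    """Metabolite formation as a percentage of the (water) control."""
    if control_amount <= 0:
        raise ValueError("control amount must be > 0")
    return 100.0 * test_amount / control_amount


def read_timecourse_csv(source) -> TimeCourse:
    """Read a ``time_min, replicate, concentration`` CSV into a TimeCourse."""
    df = pd.read_csv(source)
    required = {"time_min", "replicate", "concentration"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    wide = df.pivot_table(
        index="replicate", columns="time_min", values="concentration"
    ).sort_index(axis=1)
    return TimeCourse(
        timepoints=tuple(wide.columns.astype(float)),
        concentrations=tuple(map(tuple, wide.to_numpy())),
    )
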