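"""Outcome simulation: mixed-model data generator with optional time trends.

Outcomes are average weekday minutes of moderate-to-vigorous physical
activity (MVPA).  For pupil j of school i measured at period t,

    y_ijt = baseline_mean + trend(calendar_t) + effect * treated_it
            + u_i + v_it + w_ij + e_ijt

with independent zero-mean Gaussian draws whose variances are the four
components of :class:`~swedge.variance.VarianceComponents`.  The pupil draw
``w_ij`` is held fixed across occasions (cohort designs); the school-period
draw ``v_it`` is shared by all pupils of a school in one period.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .cohort import CohortScheme, design_membership
from .design import DesignConfiguration
from .variance import VarianceComponents

__all__ = ["TimeTrend", "seasonal_trend", "secular_trend", "no_trend", "simulate_dataset"]


def _default_knots() -> np.ndarray:
    """Monthly knot heights of the packaged seasonal shape (summer peak)."""
    from importlib import resources

    path = resources.files("swedge") / "fixtures" / "seasonal_knots.csv"
    table = pd.read_csv(str(path), comment="#")
    return table.sort_values("month")["height"].to_numpy(dtype=float)


@dataclass
class TimeTrend:
    """Additive mean offset over time.

    ``evaluator`` maps (months_since_start, month_of_year) to an offset in
    MVPA minutes.  Seasonal trends are periodic in the calendar month with a
    12-month cycle and an exact peak-to-trough difference of ``amplitude``;
    secular trends are linear in time at ``slope`` minutes per year.
    """

    kind: str = "none"
    amplitude: float = 0.0
    slope: float = 0.0
    evaluator: Callable[[float, float], float] | None = None

    def __call__(self, months: float, month_of_year: float) -> float:
        if self.kind == "none":
            return 0.0
        return float(self.evaluator(months, month_of_year))


def no_trend() -> TimeTrend:
    return TimeTrend(kind="none")


def seasonal_trend(
    amplitude: float,
    peak_month: float = 7.0,
    knots: np.ndarray | None = None,
) -> TimeTrend:
    """Cyclic seasonal trend with exact peak-to-trough range ``amplitude``.

    A periodic cubic spline is interpolated through 12 monthly knot heights
    (default: a smooth single-cycle shape), rotated so its maximum falls at
    ``peak_month``, then rescaled so that max - min over one cycle equals
    ``amplitude`` and centred to zero mean over the cycle.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    heights = np.asarray(_default_knots() if knots is None else knots, dtype=float)
    if heights.size != 12:
        raise ValueError("expected 12 monthly knot heights")
    months = np.arange(1.0, 13.0)  # knots at calendar months
    spline = CubicSpline(
        np.append(months, 13.0),
        np.append(heights, heights[0]),
        bc_type="periodic",
    )
    grid = np.linspace(0.0, 12.0, 2401)
    vals = spline((grid - 1.0) % 12.0 + 1.0)
    lo, hi = vals.min(), vals.max()
    if hi - lo == 0:
        scale, offset = 0.0, 0.0
    else:
        scale = amplitude / (hi - lo)
        offset = vals.mean() * scale
    raw_peak = grid[np.argmax(vals)]
    evaluator = _SeasonalEvaluator(spline, scale, offset, peak_month - raw_peak)
    return TimeTrend(kind="seasonal", amplitude=amplitude, evaluator=evaluator)


@dataclass
class _SeasonalEvaluator:
    """Picklable cyclic evaluator (month-of-year axis)."""

    spline: CubicSpline
    scale: float
    offset: float
    shift: float

    def __call__(self, months_since_start, month_of_year):
        m = (np.asarray(month_of_year) - self.shift - 1.0) % 12.0 + 1.0
        return self.spline(m) * self.scale - self.offset


@dataclass
class _SecularEvaluator:
    """Picklable linear-in-time evaluator."""

    slope_per_year: float

    def __call__(self, months_since_start, month_of_year):
        return self.slope_per_year * np.asarray(months_since_start) / 12.0


def secular_trend(slope_per_year: float) -> TimeTrend:
    """Linear background trend in minutes per year (zero at study start)."""
    return TimeTrend(
        kind="secular", slope=slope_per_year, evaluator=_SecularEvaluator(slope_per_year)
    )


def simulate_dataset(
    design: DesignConfiguration,
    components: VarianceComponents,
    trend: TimeTrend,
    effect: float,
    baseline_mean: float,
    scheme: CohortScheme,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate one pupil-period outcome dataset for a design.

    Returns a tidy frame with columns school, sequence, period, months,
    month_of_year, pupil, treatment, outcome — one row per present pupil at
    each measured occasion of its school.  Random draws are made in a fixed
    order (membership, then school, school-period, pupil, residual effects,
    each in id order) so one generator state determines the dataset exactly.
    """
    if scheme.kind == "cross_sectional" and components.var_pupil > 0:
        # pupils are never remeasured: pupil variance folds into the residual
        components = VarianceComponents(
            components.var_school,
            components.var_school_time,
            0.0,
            components.var_resid + components.var_pupil,
        )
    membership = design_membership(scheme, design, rng)
    rows = membership[membership["present"]].drop(columns="present")

    n_schools = design.total_schools
    treated = design.treated

    school_eff = rng.normal(0.0, np.sqrt(components.var_school), size=n_schools)
    st_eff = rng.normal(
        0.0, np.sqrt(components.var_school_time), size=(n_schools, design.n_periods)
    )
    # stable pupil draws: one per (school, eligible pupil id)
    if components.var_pupil > 0:
        pupil_eff = rng.normal(
            0.0, np.sqrt(components.var_pupil), size=(n_schools, scheme.eligible_per_school)
        )
    else:
        pupil_eff = np.zeros((n_schools, 1))

    school = rows["school"].to_numpy()
    period = rows["occasion"].to_numpy()
    seq = rows["sequence"].to_numpy()
    pupil = rows["pupil"].to_numpy()

    resid = rng.normal(0.0, np.sqrt(components.var_resid), size=len(rows))

    months = np.array([lab.months for lab in design.period_labels])
    moy = np.array([lab.month_of_year for lab in design.period_labels])
    trend_by_period = np.array(
        [trend(months[p], moy[p]) for p in range(design.n_periods)]
    )
    treat = treated[seq, period].astype(int)

    outcome = (
        baseline_mean
        + trend_by_period[period]
        + effect * treat
        + school_eff[school]
        + st_eff[school, period]
        + (pupil_eff[school, pupil] if components.var_pupil > 0 else 0.0)
        + resid
    )
    return pd.DataFrame(
        {
            "school": school,
            "sequence": seq,
            "period": period,
            "months": months[period],
            "month_of_year": moy[period],
            "pupil": pupil,
            "treatment": treat,
            "outcome": outcome,
        }
    )
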