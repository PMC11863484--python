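"""Variance decomposition for the school / school-time / pupil / residual model.

The data-generating and analysis models carry four random components whose
sizes are parameterised, as is conventional in the cluster-trial literature,
by the total outcome SD together with three correlations:

* ICC  — share of total variance attributable to schools at one time point,
* CAC  — correlation of a school's true means at two time points,
* IAC  — correlation of a pupil's outcomes at two time points net of school
         effects (cohort designs only).

The mapping to components is::

    var_school      = cac * icc * sd**2          (time-stable school)
    var_school_time = (1 - cac) * icc * sd**2    (school-by-period)
    var_pupil       = iac * (1 - icc) * sd**2    (time-stable pupil)
    var_resid       = (1 - iac) * (1 - icc) * sd**2

which always sums to ``sd**2``.  For cross-sectional designs pupils are never
remeasured, so the pupil component is folded into the residual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CorrelationSpec",
    "VarianceComponents",
    "decompose",
    "correlations_from_components",
    "empirical_correlations",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationSpec:
    """Total SD plus ICC / CAC / IAC correlation parameterisation."""

    sd_total: float
    icc: float
    cac: float = 1.0
    iac: float = 0.0

    def __post_init__(self) -> None:
        if not self.sd_total > 0:
            raise ValueError("sd_total must be positive")
        if not 0 <= self.icc < 1:
            raise ValueError(f"icc must be in [0, 1), got {self.icc}")
        if not 0 <= self.cac <= 1:
            raise ValueError(f"cac must be in [0, 1], got {self.cac}")
        if not 0 <= self.iac <= 1:
            raise ValueError(f"iac must be in [0, 1], got {self.iac}")


@dataclass(frozen=True)
class VarianceComponents:
    """The four variance components, in squared outcome units."""

    var_school: float
    var_school_time: float
    var_pupil: float
    var_resid: float

    @property
    def total(self) -> float:
        return self.var_school + self.var_school_time + self.var_pupil + self.var_resid

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.var_school, self.var_school_time, self.var_pupil, self.var_resid]
        )


def decompose(spec: CorrelationSpec, cohort_kind: str = "closed") -> VarianceComponents:
    """Convert a :class:`CorrelationSpec` into the four variance components.

    For ``cohort_kind='cross_sectional'`` the IAC is ignored (with a logged
    notice if nonzero) and pupil variance is folded into the residual.
    """
    if cohort_kind not in ("cross_sectional", "closed", "open"):
        raise ValueError(f"unknown cohort kind {cohort_kind!r}")
    v = spec.sd_total**2
    vs = spec.cac * spec.icc * v
    vst = (1 - spec.cac) * spec.icc * v
    if cohort_kind == "cross_sectional":
        if spec.iac:
            log.info(
                "cross-sectional design: iac=%g ignored, pupil variance folded "
                "into residual",
                spec.iac,
            )
        vp, ve = 0.0, (1 - spec.icc) * v
    else:
        vp = spec.iac * (1 - spec.icc) * v
        ve = (1 - spec.iac) * (1 - spec.icc) * v
    return VarianceComponents(vs, vst, vp, ve)


def correlations_from_components(components: VarianceComponents) -> CorrelationSpec:
    """Inverse of :func:`decompose` (pupil variance treated as cohort-style)."""
    total = components.total
    icc = (components.var_school + components.var_school_time) / total
    cac = components.var_school / (components.var_school + components.var_school_time) if icc else 1.0
    within = components.var_pupil + components.var_resid
    iac = components.var_pupil / within if within else 0.0
    return CorrelationSpec(np.sqrt(total), icc, cac, iac)


def empirical_correlations(dataset: pd.DataFrame) -> dict:
    """Method-of-moments ICC / CAC / IAC estimates from a simulated dataset.

    Estimates are built from school-period means and pupil-level residuals:

    * school-level variance is decomposed into a time-stable part (covariance
      of a school's means across period pairs) and a period-specific part;
      ICC is their sum over the total variance and CAC their ratio;
    * IAC is the within-pupil cross-period covariance of outcomes net of
      school-period means, over the within-school variance.

    Estimates that cannot be formed (single period, no repeated pupils) are
    returned as ``None`` rather than silently zero.

    Parameters
    ----------
    dataset : DataFrame with columns school, period, pupil, treatment, outcome
        (the layout produced by :func:`swedge.datagen.simulate_dataset`);
        any fixed-effect structure is removed via cell means, so the
        estimates assume the fixed part is constant within school-period
        cells, which holds for the generator.
    """
    df = dataset.copy()
    n_periods = df["period"].nunique()
    # remove fixed effects (mean structure) within period x treatment cells
    df["dev"] = df["outcome"] - df.groupby(["period", "treatment"])["outcome"].transform("mean")

    cell = df.groupby(["school", "period"])["dev"].agg(["mean", "var", "count"])
    within_cell_var = float(
        np.average(cell["var"].dropna(), weights=cell["count"][cell["var"].notna()] - 1)
    )
    nbar = float(cell["count"].mean())

    # pupil-stable variance: within-pupil covariance across periods, net of
    # school-period means
    df["cdev"] = df["dev"] - df.groupby(["school", "period"])["dev"].transform("mean")
    pupil_wide = df.pivot_table(
        index=["school", "pupil"], columns="period", values="cdev"
    )
    pcov = pupil_wide.cov()
    poff = pcov.values[~np.eye(pcov.shape[0], dtype=bool)]
    var_pupil = float(np.nanmean(poff)) if poff.size and not np.all(np.isnan(poff)) else None

    wide = cell["mean"].unstack("period")
    # covariance of school-period means across distinct period pairs carries
    # the time-stable school variance plus, when pupils repeat, a shared
    # pupil-mean term of order var_pupil / n that must be removed; the
    # diagonal adds the period-specific school variance and a within-cell
    # mean term of order 1/n
    cov = wide.cov()
    off = cov.values[~np.eye(cov.shape[0], dtype=bool)]
    diag = np.diag(cov.values)
    if not off.size:
        return {"icc": None, "cac": None, "iac": None}
    var_school = float(off.mean()) - (var_pupil or 0.0) / nbar
    var_school_time = float(diag.mean()) - var_school - within_cell_var / nbar

    var_school = max(var_school, 0.0)
    var_school_time = max(var_school_time, 0.0)
    total_school = var_school + var_school_time
    total = total_school + within_cell_var
    out = {
        "icc": total_school / total,
        "cac": var_school / total_school if total_school > 0 else None,
        "iac": None,
    }
    if var_pupil is not None and n_periods >= 2:
        out["iac"] = max(var_pupil, 0.0) / within_cell_var
    return out
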