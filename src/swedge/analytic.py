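"""Closed-form power: GLS on cluster-period means, cluster search, CRCT.

For shortlisting designs the variance of the GLS treatment-effect estimator
is computed from the covariance of each cluster's measured cluster-period
means (the standard framework for stepped wedge sample-size work):

* diagonal:      var_school + var_school_time + (var_pupil + var_resid) / n
* off-diagonal:  var_school + overlap * var_pupil / n

where ``n`` is the per-occasion pupil count and ``overlap`` the expected
fraction of pupils shared between two occasions (1 for a closed cohort, the
retention rate for the open scheme, 0 for cross-sectional).  Unmeasured
cluster-period cells are simply deleted from the GLS system.  Fixed effects
are categorical period effects plus treatment; power uses the normal
approximation Phi(|effect| / SE - z_{1-alpha/2}).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .design import DesignConfiguration
from .variance import VarianceComponents

__all__ = [
    "AnalyticPowerSpec",
    "gls_effect_variance",
    "power_from_variance",
    "analytic_power",
    "required_clusters",
    "crct_power_baseline_adjusted",
]


@dataclass(frozen=True)
class AnalyticPowerSpec:
    """Inputs for closed-form power on one design."""

    design: DesignConfiguration
    n_per_cell: int  # pupils measured per cluster-period cell (constant)
    components: VarianceComponents
    effect: float
    alpha: float = 0.05
    cohort_kind: str = "closed"
    retention_rate: float = 1.0  # used for open-cohort overlap only

    def __post_init__(self) -> None:
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be at least 1")
        if self.cohort_kind not in ("cross_sectional", "closed", "open"):
            raise ValueError(f"unknown cohort kind {self.cohort_kind!r}")

    @property
    def overlap(self) -> float:
        if self.cohort_kind == "closed":
            return 1.0
        if self.cohort_kind == "open":
            return self.retention_rate
        return 0.0


def gls_effect_variance(spec: AnalyticPowerSpec) -> float:
    """Variance (min^2) of the GLS treatment-effect estimator."""
    d = spec.design
    d.validate()
    c = spec.components
    n = spec.n_per_cell
    diag = c.var_school + c.var_school_time + (c.var_pupil + c.var_resid) / n
    off = c.var_school + spec.overlap * c.var_pupil / n

    T = d.n_periods
    p = 1 + (T - 1) + 1  # intercept + period effects + treatment
    info = np.zeros((p, p))
    meas, treat = d.measured, d.treated
    for s in range(d.n_sequences):
        periods = np.flatnonzero(meas[s])
        m = periods.size
        if m == 0:
            continue
        V = np.full((m, m), off)
        np.fill_diagonal(V, diag)
        X = np.zeros((m, p))
        X[:, 0] = 1.0
        for i, t in enumerate(periods):
            if t > 0:
                X[i, t] = 1.0
            X[i, -1] = float(treat[s, t])
        info += d.allocation[s] * X.T @ np.linalg.solve(V, X)
    # drop all-zero period columns (periods never measured) before inverting
    keep = np.flatnonzero(np.abs(info).sum(axis=0) > 0)
    info = info[np.ix_(keep, keep)]
    sign, _ = np.linalg.slogdet(info)
    if sign <= 0 or np.linalg.cond(info) > 1e12:
        raise ValueError(
            "singular information: design has no control/intervention contrast"
        )
    return float(np.linalg.inv(info)[-1, -1])


def power_from_variance(effect: float, variance: float, alpha: float = 0.05) -> float:
    """Normal-approximation power Phi(|effect|/SE - z_{1-alpha/2}).

    At effect 0 this returns alpha/2 (the one-sided crossing probability);
    the two-sided type-I error is alpha.
    """
    if variance <= 0:
        raise ValueError("variance must be positive")
    z = norm.ppf(1 - alpha / 2)
    return float(norm.cdf(abs(effect) / np.sqrt(variance) - z))


def analytic_power(spec: AnalyticPowerSpec) -> float:
    return power_from_variance(spec.effect, gls_effect_variance(spec), spec.alpha)


def required_clusters(
    spec: AnalyticPowerSpec, target_power: float, max_clusters: int = 1000
) -> int:
    """Smallest total cluster count (balanced across sequences) reaching
    ``target_power`` under the analytic approximation."""
    if not spec.alpha < target_power < 1:
        raise ValueError("target_power must be between alpha and 1")
    k_seq = spec.design.n_sequences
    base = spec.design.with_allocation(np.ones(k_seq, dtype=int))
    unit_var = gls_effect_variance(
        AnalyticPowerSpec(
            base,
            spec.n_per_cell,
            spec.components,
            spec.effect,
            spec.alpha,
            spec.cohort_kind,
            spec.retention_rate,
        )
    )
    for total in range(k_seq, max_clusters + 1, k_seq):
        # balanced allocation scales the information linearly
        var = unit_var / (total / k_seq)
        if power_from_variance(spec.effect, var, spec.alpha) >= target_power:
            return total
    raise ValueError(f"target power not attainable with {max_clusters} clusters")


def crct_power_baseline_adjusted(
    effect: float,
    sd: float,
    icc_adjusted: float,
    pupils_per_school: int,
    schools_total: int,
    alpha: float = 0.05,
) -> dict:
    """Two-arm parallel cluster-RCT comparator, baseline-adjusted analysis.

    Power for a follow-up comparison of two arms of ``schools_total / 2``
    schools with ``pupils_per_school`` pupils each, where the baseline
    adjustment is folded into the supplied residual ICC (the convention of
    quoting a baseline-adjusted ICC with the unchanged total SD).  Uses the
    design effect 1 + (n - 1) * ICC and a normal approximation.  Also returns
    the minimum detectable difference at 80% power.
    """
    if schools_total % 2:
        raise ValueError("schools_total must split evenly into two arms")
    if not 0 <= icc_adjusted < 1:
        raise ValueError("icc_adjusted must be in [0, 1)")
    n, k = pupils_per_school, schools_total // 2
    deff = 1 + (n - 1) * icc_adjusted
    var_diff = 2 * sd**2 * deff / (n * k)
    z = norm.ppf(1 - alpha / 2)
    power = float(norm.cdf(abs(effect) / np.sqrt(var_diff) - z))
    mdd80 = float((z + norm.ppf(0.80)) * np.sqrt(var_diff))
    return {
        "power": power,
        "design_effect": deff,
        "se_difference": float(np.sqrt(var_diff)),
        "mdd_80": mdd80,
    }
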