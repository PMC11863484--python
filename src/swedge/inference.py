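"""Analysis model: linear mixed model with flexible time trend, REML fit.

The analysis model mirrors the data-generating model: fixed effects are an
intercept, a time-trend term (spline or categorical period effects) and the
intervention indicator; random intercepts are school, school-period (nested
in school) and, for cohort designs, pupil (nested in school).  The
intervention effect is tested with a two-sided Wald test against a standard
normal reference.

Two fitting backends are provided.  The default is a profiled-REML solver
written for this structure: the restricted likelihood is profiled over the
residual variance and maximised over the log variance ratios, with each
school's contribution reduced via the Woodbury identity so one likelihood
evaluation costs a small batched Cholesky factorisation.  This makes a fit
take milliseconds, which the replicate simulation loop needs.  The
``statsmodels`` backend fits the identical model with
:class:`statsmodels.regression.mixed_linear_model.MixedLM` and is used as an
independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import minimize
from scipy.stats import norm

from .variance import VarianceComponents

__all__ = [
    "TimeBasis",
    "FitResult",
    "build_time_basis",
    "fit_mixed_model",
    "wald_test",
    "UnidentifiableError",
]


class UnidentifiableError(ValueError):
    """The intervention effect cannot be estimated from this dataset."""


# ---------------------------------------------------------------------------
# time basis
# ---------------------------------------------------------------------------


@dataclass
class TimeBasis:
    """Evaluated time-trend basis columns per distinct calendar position.

    ``columns`` enter the model as fixed effects.  For the penalized
    thin-plate kind, ``penalized`` holds additional smooth-deviation columns
    whose coefficients are treated as a zero-mean random effect with a
    REML-estimated variance — the mixed-model form of penalized smoothing,
    so the effective flexibility of the time adjustment is learned from the
    data (shrinking to the linear null space when there is no trend).
    """

    kind: str
    df: int
    positions: np.ndarray  # distinct calendar positions (months), sorted
    columns: np.ndarray  # (n_positions, df) fixed basis, intercept excluded
    penalized: np.ndarray | None = None  # (n_positions, q) smooth deviations

    def _rows(self, matrix: np.ndarray, months: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.positions, months)
        if not np.allclose(self.positions[np.clip(idx, 0, len(self.positions) - 1)], months):
            raise ValueError("position not in the basis grid")
        return matrix[idx]

    def expand(self, months: np.ndarray) -> np.ndarray:
        """Fixed-effect basis rows for arbitrary observed positions."""
        return self._rows(self.columns, months)

    def expand_penalized(self, months: np.ndarray) -> np.ndarray | None:
        if self.penalized is None:
            return None
        return self._rows(self.penalized, months)


def build_time_basis(
    calendar_positions,
    kind: str = "fixed_df_spline",
    df: int = 4,
) -> TimeBasis:
    """Deterministic time basis over the distinct calendar positions.

    ``categorical_period`` gives one indicator per position with the first
    (reference) level dropped; ``fixed_df_spline`` gives a cubic B-spline
    basis of rank ``df`` (intercept column removed); with only two distinct
    positions any smooth basis degenerates to a single linear column.
    """
    pos = np.unique(np.asarray(calendar_positions, dtype=float))
    k = pos.size
    if k < 2:
        raise ValueError("need at least 2 distinct calendar positions")
    if kind == "categorical_period":
        cols = np.eye(k)[:, 1:]
        return TimeBasis(kind, k - 1, pos, cols)
    if kind == "penalized_thin_plate":
        span = pos[-1] - pos[0]
        lin = ((pos - pos[0]) / span)[:, None]
        if k == 2:
            return TimeBasis(kind, 1, pos, lin)
        # low-rank thin-plate spline, mixed-model form: radial basis |x - k|^3
        # at the distinct positions, whitened by the penalty so that the
        # smooth coefficients are iid; null space (intercept + linear) stays fixed
        x = (pos - pos[0]) / span
        R = np.abs(x[:, None] - x[None, :]) ** 3
        w, V = np.linalg.eigh(R)
        keep = np.abs(w) > 1e-10 * np.abs(w).max()
        Z = R @ V[:, keep] @ np.diag(1.0 / np.sqrt(np.abs(w[keep]))) @ V[:, keep].T
        return TimeBasis(kind, 1, pos, lin, penalized=Z)
    if kind != "fixed_df_spline":
        raise ValueError(f"unknown basis kind {kind!r}")
    if df >= k:
        raise ValueError(f"df={df} too large for {k} distinct positions")
    if k == 2 or df == 1:
        cols = ((pos - pos[0]) / (pos[-1] - pos[0]))[:, None]
        return TimeBasis(kind, 1, pos, cols)
    degree = min(3, df)
    n_interior = df - degree
    lo, hi = pos[0], pos[-1]
    if n_interior > 0:
        interior = np.quantile(pos, np.linspace(0, 1, n_interior + 2)[1:-1])
    else:
        interior = np.array([])
    knots = np.concatenate(
        [np.repeat(lo, degree + 1), interior, np.repeat(hi, degree + 1)]
    )
    n_basis = len(knots) - degree - 1  # == df + 1, including the intercept
    full = np.empty((k, n_basis))
    for j in range(n_basis):
        coef = np.zeros(n_basis)
        coef[j] = 1.0
        full[:, j] = BSpline(knots, coef, degree)(pos)
    cols = full[:, 1:]  # drop one column; remainder independent of intercept
    if np.linalg.matrix_rank(np.column_stack([np.ones(k), cols])) != df + 1:
        raise ValueError("basis columns are rank deficient")
    return TimeBasis(kind, df, pos, cols)


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Intervention-effect estimate and test from one mixed-model fit."""

    effect_estimate: float
    std_error: float
    p_value: float
    reject: bool
    converged: bool
    variance_component_estimates: VarianceComponents
    alpha: float = 0.05
    singular: bool = False  # a variance component at the zero boundary
    n_obs: int = 0
    smooth_variance: float | None = None  # penalized time-smooth variance


def wald_test(fit: FitResult, alpha: float = 0.05) -> dict:
    """Two-sided normal-reference Wald test on the intervention effect."""
    if not fit.converged:
        raise ValueError("no test decision from a non-converged fit")
    z = fit.effect_estimate / fit.std_error
    p = 2.0 * norm.sf(abs(z))
    return {"z": z, "p_value": p, "reject": bool(p < alpha)}


# ---------------------------------------------------------------------------
# profiled-REML solver
# ---------------------------------------------------------------------------

_LOG_LO, _LOG_HI = -12.0, 8.0


def _design_matrices(dataset: pd.DataFrame, basis: TimeBasis):
    months = dataset["months"].to_numpy()
    treat = dataset["treatment"].to_numpy(dtype=float)
    if treat.min() == treat.max():
        raise UnidentifiableError(
            "treatment is constant: dataset has no control/intervention contrast"
        )
    X = np.column_stack([np.ones(len(dataset)), basis.expand(months), treat])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise UnidentifiableError("fixed-effect design is rank deficient")
    return X, dataset["outcome"].to_numpy(), basis.expand_penalized(months)


def _school_blocks(dataset: pd.DataFrame, X: np.ndarray, y: np.ndarray, with_pupil: bool):
    """Sufficient statistics for the Woodbury-reduced REML objective.

    For school i with random-effect incidence U_i = [1 | periods | pupils]
    the statistics (U'U, U'[X y], X'X, X'y, y'y, component sizes) fully
    determine the objective at any variance ratio.  Schools with identical
    component sizes are stacked so one likelihood evaluation is a single
    batched Cholesky factorisation.
    """
    p = X.shape[1]
    per_school = []
    XtX = np.zeros((p, p))
    Xty = np.zeros(p)
    yty = 0.0
    for _, sub in dataset.groupby("school", sort=True):
        idx = sub.index.to_numpy()
        Xi, yi = X[idx], y[idx]
        n = len(sub)
        periods = pd.factorize(sub["period"], sort=True)[0]
        cols = [np.ones((n, 1))]
        sizes = [1]
        T = periods.max() + 1
        Zt = np.zeros((n, T))
        Zt[np.arange(n), periods] = 1.0
        cols.append(Zt)
        sizes.append(T)
        if with_pupil:
            pupils = pd.factorize(sub["pupil"], sort=True)[0]
            P = pupils.max() + 1
            Zp = np.zeros((n, P))
            Zp[np.arange(n), pupils] = 1.0
            cols.append(Zp)
            sizes.append(P)
        U = np.hstack(cols)
        Xy = np.column_stack([Xi, yi])
        per_school.append((tuple(sizes), U.T @ U, U.T @ Xy))
        XtX += Xi.T @ Xi
        Xty += Xi.T @ yi
        yty += float(yi @ yi)

    groups = {}
    for sizes, UtU, UtXy in per_school:
        groups.setdefault(sizes, []).append((UtU, UtXy))
    stacked = [
        {
            "sizes": np.array(sizes),
            "UtU": np.stack([g[0] for g in grp]),
            "UtXy": np.stack([g[1] for g in grp]),
        }
        for sizes, grp in groups.items()
    ]
    return {"groups": stacked, "XtX": XtX, "Xty": Xty, "yty": yty, "p": p}


def _reml_pieces(blocks, gammas):
    """X'W^-1X, X'W^-1y, y'W^-1y and sum of log|W_i| over schools."""
    p = blocks["p"]
    G = np.zeros((p + 1, p + 1))
    logdet = 0.0
    for grp in blocks["groups"]:
        sizes = grp["sizes"]
        dinv = np.repeat(1.0 / gammas, sizes)
        M = grp["UtU"] + np.diag(dinv)[None, :, :]
        L = np.linalg.cholesky(M)
        k = M.shape[0]
        logdet += 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum()
        logdet += k * float(sizes @ np.log(gammas))
        S = np.linalg.solve(M, grp["UtXy"])
        G += np.einsum("kmi,kmj->ij", grp["UtXy"], S)
    A = blocks["XtX"] - G[:p, :p]
    b = blocks["Xty"] - G[:p, p]
    c = blocks["yty"] - G[p, p]
    return A, b, c, logdet


def _fit_reml(dataset: pd.DataFrame, basis: TimeBasis, alpha: float):
    X, y, Zg = _design_matrices(dataset, basis)
    dataset = dataset.reset_index(drop=True)
    with_pupil = bool(
        dataset.groupby(["school", "pupil"])["period"].nunique().max() > 1
    )
    N, p = X.shape
    q = Zg.shape[1] if Zg is not None else 0
    Xa = np.column_stack([X, Zg]) if q else X
    blocks = _school_blocks(dataset, Xa, y, with_pupil)
    n_comp = 3 if with_pupil else 2

    def profile(phi):
        """A = X'W^-1X, b = X'W^-1y, c = y'W^-1y, log|W| at variance ratios.

        The global smooth-deviation component (penalized time basis) is
        folded in with a second Woodbury layer on top of the per-school
        block reduction.
        """
        gammas = np.exp(np.clip(phi[:n_comp], _LOG_LO, _LOG_HI))
        A_, b_, c_, logdet = _reml_pieces(blocks, gammas)
        if not q:
            return A_, b_, c_, logdet
        gam_t = float(np.exp(np.clip(phi[n_comp], _LOG_LO, _LOG_HI)))
        Axx, Axz, Azz = A_[:p, :p], A_[:p, p:], A_[p:, p:]
        bx, bz = b_[:p], b_[p:]
        K = Azz + np.eye(q) / gam_t
        S = np.linalg.solve(K, np.column_stack([Axz.T, bz[:, None]]))
        A = Axx - Axz @ S[:, :p]
        b = bx - Axz @ S[:, p]
        c = c_ - bz @ S[:, p]
        sign, ld_K = np.linalg.slogdet(K)
        if sign <= 0:
            return None
        logdet += ld_K + q * np.log(gam_t)
        return A, b, c, logdet

    def neg2_reml(phi):
        pieces = profile(phi)
        if pieces is None:
            return np.inf
        A, b, c, logdet = pieces
        sign, ld_A = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(A, b)
        rss = c - b @ beta
        if rss <= 0:
            return np.inf
        return logdet + ld_A + (N - p) * np.log(rss)

    x0 = np.concatenate(
        [np.log([0.08, 0.03, 0.6])[:n_comp], np.log([0.01])[: (1 if q else 0)]]
    )
    res = minimize(
        neg2_reml,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 600},
    )
    phi = np.clip(res.x, _LOG_LO, _LOG_HI)
    A, b, c, _ = profile(phi)
    beta = np.linalg.solve(A, b)
    sigma2 = (c - b @ beta) / (N - p)
    cov = sigma2 * np.linalg.inv(A)
    est, se = float(beta[-1]), float(np.sqrt(cov[-1, -1]))
    z = est / se
    pval = 2.0 * norm.sf(abs(z))
    gammas = np.exp(phi[:n_comp])
    singular = bool(np.any(phi[:n_comp] <= _LOG_LO + 1e-9))
    comp = gammas * sigma2
    vc = VarianceComponents(
        float(comp[0]),
        float(comp[1]),
        float(comp[2]) if with_pupil else 0.0,
        float(sigma2),
    )
    return FitResult(
        effect_estimate=est,
        std_error=se,
        p_value=float(pval),
        reject=bool(pval < alpha),
        converged=bool(res.success),
        variance_component_estimates=vc,
        alpha=alpha,
        singular=singular,
        n_obs=N,
        smooth_variance=float(np.exp(phi[n_comp]) * sigma2) if q else None,
    )


def _fit_statsmodels(dataset: pd.DataFrame, basis: TimeBasis, alpha: float):
    import statsmodels.formula.api as smf

    X, _, Zg = _design_matrices(dataset, basis)
    if Zg is not None:
        raise NotImplementedError(
            "penalized time basis is only supported by the fast backend"
        )
    df = dataset.reset_index(drop=True).copy()
    bnames = []
    for j in range(1, X.shape[1] - 1):
        name = f"tb{j}"
        df[name] = X[:, j]
        bnames.append(name)
    with_pupil = bool(df.groupby(["school", "pupil"])["period"].nunique().max() > 1)
    vc = {"schoolperiod": "0 + C(period)"}
    if with_pupil:
        vc["pupil"] = "0 + C(pupil)"
    formula = "outcome ~ " + " + ".join(bnames + ["treatment"])
    model = smf.mixedlm(formula, df, groups="school", re_formula="1", vc_formula=vc)
    fit = model.fit(reml=True, method="lbfgs", maxiter=500)
    est = float(fit.params["treatment"])
    se = float(fit.bse["treatment"])
    z = est / se
    pval = 2.0 * norm.sf(abs(z))
    sigma2 = float(fit.scale)
    vcs = dict(zip(model.exog_vc.names, np.atleast_1d(fit.vcomp)))
    comp = VarianceComponents(
        float(fit.cov_re.iloc[0, 0]),
        float(vcs["schoolperiod"]),
        float(vcs.get("pupil", 0.0)),
        sigma2,
    )
    return FitResult(
        effect_estimate=est,
        std_error=se,
        p_value=float(pval),
        reject=bool(pval < alpha),
        converged=bool(fit.converged),
        variance_component_estimates=comp,
        alpha=alpha,
        n_obs=len(df),
    )


def fit_mixed_model(
    dataset: pd.DataFrame,
    basis: TimeBasis | None = None,
    alpha: float = 0.05,
    backend: str = "fast",
    components: VarianceComponents | None = None,
) -> FitResult:
    """Fit the analysis mixed model and test the intervention effect.

    Parameters
    ----------
    dataset : simulated outcome frame (see :func:`swedge.datagen.simulate_dataset`)
    basis : time basis; default is a df-4 regression spline over the
        dataset's distinct calendar positions (categorical periods if there
        are too few distinct positions for df 4)
    backend : ``'fast'`` (profiled REML, default) or ``'statsmodels'``
    components : if given, skip variance estimation and compute the GLS
        estimate at these known components (exact-recovery and oracle tests)
    """
    if dataset.empty:
        raise UnidentifiableError("empty dataset")
    if basis is None:
        # default adjustment: free period effects when the design has few
        # distinct occasions (the textbook discrete-time analysis); a
        # penalized thin-plate smooth over the school-year calendar when
        # time is effectively continuous (7+ positions spanning seasonality)
        k = dataset["months"].nunique()
        kind = "penalized_thin_plate" if k >= 7 else "categorical_period"
        basis = build_time_basis(dataset["months"].unique(), kind)
    if components is not None:
        return _fit_known_components(dataset, basis, alpha, components)
    if backend == "fast":
        return _fit_reml(dataset, basis, alpha)
    if backend == "statsmodels":
        return _fit_statsmodels(dataset, basis, alpha)
    raise ValueError(f"unknown backend {backend!r}")


def _fit_known_components(dataset, basis, alpha, components: VarianceComponents):
    X, y, Zg = _design_matrices(dataset, basis)
    if Zg is not None:
        # with known components there is no smoothing parameter to estimate;
        # the smooth deviations enter unpenalized
        X = np.column_stack([X[:, :-1], Zg, X[:, -1]])
    dataset = dataset.reset_index(drop=True)
    with_pupil = components.var_pupil > 0
    blocks = _school_blocks(dataset, X, y, with_pupil)
    ve = components.var_resid
    gammas = np.array(
        [components.var_school, components.var_school_time]
        + ([components.var_pupil] if with_pupil else [])
    ) / ve
    gammas = np.maximum(gammas, np.exp(_LOG_LO))
    A, b, _, _ = _reml_pieces(blocks, gammas)
    beta = np.linalg.solve(A, b)
    cov = ve * np.linalg.inv(A)
    est, se = float(beta[-1]), float(np.sqrt(cov[-1, -1]))
    z = est / se
    pval = 2.0 * norm.sf(abs(z))
    return FitResult(
        effect_estimate=est,
        std_error=se,
        p_value=float(pval),
        reject=bool(pval < alpha),
        converged=True,
        variance_component_estimates=components,
        alpha=alpha,
        n_obs=len(dataset),
    )
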