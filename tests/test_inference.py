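"""Mixed-model fitting: bases, exact recovery, oracles, cross-checks."""

import numpy as np
import pytest

from swedge.cohort import CohortScheme
from swedge.datagen import no_trend, simulate_dataset
from swedge.design import build_complete_design
from swedge.inference import (
    UnidentifiableError,
    build_time_basis,
    fit_mixed_model,
    wald_test,
    FitResult,
)
from swedge.variance import CorrelationSpec, VarianceComponents, decompose

MONTHS7 = [-3.0, 1.0, 2.5, 4.5, 6.0, 7.5, 9.0]


class TestTimeBasis:
    def test_categorical_reference_coding(self):
        basis = build_time_basis(MONTHS7, "categorical_period")
        assert basis.columns.shape == (7, 6)
        assert basis.columns[0].sum() == 0  # reference level dropped

    def test_fixed_df_spline_rank(self):
        basis = build_time_basis(MONTHS7, "fixed_df_spline", df=3)
        assert basis.columns.shape == (7, 3)
        full = np.column_stack([np.ones(7), basis.columns])
        assert np.linalg.matrix_rank(full) == 4

    def test_two_positions_reduce_to_linear(self):
        for kind in ("fixed_df_spline", "penalized_thin_plate"):
            basis = build_time_basis([0.0, 6.0], kind, df=1)
            assert basis.columns.shape == (2, 1)
            assert basis.penalized is None

    def test_penalized_basis_shapes(self):
        basis = build_time_basis(MONTHS7, "penalized_thin_plate")
        assert basis.columns.shape == (7, 1)
        assert basis.penalized.shape[0] == 7

    def test_df_too_large_rejected(self):
        with pytest.raises(ValueError):
            build_time_basis(MONTHS7, "fixed_df_spline", df=7)


@pytest.fixture(scope="module")
def study_components():
    return decompose(CorrelationSpec(23.0, 0.08, 0.75, 0.45), "closed")


@pytest.fixture(scope="module")
def small_dataset(study_components):
    # large enough that the REML surface has an interior optimum both
    # backends find; tiny datasets sit on variance boundaries where
    # optimizer idiosyncrasies dominate
    design = build_complete_design(5, allocation=2)
    scheme = CohortScheme("closed", 12)
    return simulate_dataset(
        design, study_components, no_trend(), 5.0, 100.0, scheme,
        np.random.default_rng(12),
    )


class TestFitMixedModel:
    def test_noise_free_exact_recovery(self):
        design = build_complete_design(3, allocation=2)
        zero = VarianceComponents(0, 0, 0, 0)
        data = simulate_dataset(
            design, zero, no_trend(), 5.0, 100.0, CohortScheme("closed", 4),
            np.random.default_rng(0),
        )
        fit = fit_mixed_model(data)
        assert fit.effect_estimate == pytest.approx(5.0, abs=1e-6)
        assert fit.reject

    def test_agrees_with_statsmodels_reml(self, small_dataset):
        """Dual-route check: the profiled-REML solver against MixedLM."""
        basis = build_time_basis(
            sorted(small_dataset["months"].unique()), "categorical_period"
        )
        fast = fit_mixed_model(small_dataset, basis=basis, backend="fast")
        sm = fit_mixed_model(small_dataset, basis=basis, backend="statsmodels")
        assert fast.effect_estimate == pytest.approx(sm.effect_estimate, abs=1e-3)
        assert fast.std_error == pytest.approx(sm.std_error, rel=2e-3)
        est = fast.variance_component_estimates
        smv = sm.variance_component_estimates
        assert est.var_school == pytest.approx(smv.var_school, abs=0.5)
        assert est.var_resid == pytest.approx(smv.var_resid, rel=0.02)

    def test_gls_cluster_mean_oracle(self, study_components):
        """With categorical time and known components, the fitted effect
        equals a small-matrix GLS on cluster-period means."""
        design = build_complete_design(2, 3, allocation=2)
        n = 5
        data = simulate_dataset(
            design, study_components, no_trend(), 5.0, 100.0,
            CohortScheme("closed", n), np.random.default_rng(21),
        )
        basis = build_time_basis(sorted(data["months"].unique()), "categorical_period")
        fit = fit_mixed_model(data, basis=basis, components=study_components)

        # independent oracle: GLS on the school-period means
        c = study_components
        means = data.groupby(["school", "period"])["outcome"].mean()
        T = design.n_periods
        diag = c.var_school + c.var_school_time + (c.var_pupil + c.var_resid) / n
        off = c.var_school + c.var_pupil / n
        V = np.full((T, T), off)
        np.fill_diagonal(V, diag)
        rows, ys = [], []
        for school, sub in means.groupby("school"):
            seq = int(data.loc[data["school"] == school, "sequence"].iloc[0])
            X = np.zeros((T, 1 + (T - 1) + 1))
            X[:, 0] = 1
            for t in range(1, T):
                X[t, t] = 1
            X[:, -1] = design.treated[seq].astype(float)
            rows.append(X)
            ys.append(sub.to_numpy())
        Vinv = np.linalg.inv(V)
        A = sum(X.T @ Vinv @ X for X in rows)
        b = sum(X.T @ Vinv @ y for X, y in zip(rows, ys))
        beta = np.linalg.solve(A, b)
        assert fit.effect_estimate == pytest.approx(beta[-1], abs=1e-8)

    def test_location_and_scale_equivariance(self, small_dataset):
        fit = fit_mixed_model(small_dataset)
        shifted = small_dataset.assign(outcome=small_dataset["outcome"] + 37.0)
        fit_shift = fit_mixed_model(shifted)
        assert fit_shift.effect_estimate == pytest.approx(fit.effect_estimate, abs=1e-4)
        scaled = small_dataset.assign(outcome=small_dataset["outcome"] * 3.0)
        fit_scaled = fit_mixed_model(scaled)
        assert fit_scaled.effect_estimate == pytest.approx(3 * fit.effect_estimate, rel=1e-3)
        assert fit_scaled.std_error == pytest.approx(3 * fit.std_error, rel=1e-3)

    def test_constant_treatment_unidentifiable(self, study_components):
        design = build_complete_design(2, 3, allocation=1)
        data = simulate_dataset(
            design, study_components, no_trend(), 5.0, 100.0,
            CohortScheme("closed", 4), np.random.default_rng(2),
        )
        ctrl_only = data[data["treatment"] == 0]
        with pytest.raises(UnidentifiableError):
            fit_mixed_model(ctrl_only)


class TestWaldTest:
    def _fit(self, est, se):
        comp = VarianceComponents(0, 0, 0, 1)
        return FitResult(est, se, 0.5, False, True, comp)

    def test_strong_effect_rejects(self):
        out = wald_test(self._fit(5.0, 1.0), alpha=0.05)
        assert out["reject"] and out["p_value"] < 1e-6

    def test_null_estimate_never_rejects(self):
        out = wald_test(self._fit(0.0, 2.0), alpha=0.05)
        assert not out["reject"]

    def test_boundary_p_value(self):
        out = wald_test(self._fit(1.959964 * 2.0, 2.0), alpha=0.05)
        assert out["p_value"] == pytest.approx(0.05, abs=1e-5)

    def test_non_converged_gives_no_decision(self):
        fit = self._fit(5.0, 1.0)
        fit.converged = False
        with pytest.raises(ValueError):
            wald_test(fit)
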