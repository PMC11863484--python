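"""Design representation, enumeration and metrics."""

import itertools

import numpy as np
import pytest

from swedge.design import (
    CellState,
    ConstraintSet,
    build_complete_design,
    compute_design_metrics,
    enumerate_incomplete_designs,
    iter_incomplete_designs,
    read_design_csv,
    treatment_indicator,
    write_design_csv,
    IMPLEMENTATION,
    UNOBSERVED,
)


class TestCompleteDesign:
    def test_canonical_5x6_layout(self):
        d = build_complete_design(5)
        assert (d.n_sequences, d.n_periods) == (5, 6)
        assert d.measured.all()
        # sequence 0 has one control then five intervention periods
        row = d.cells[0]
        assert row[0] == CellState.CONTROL_MEASURED
        assert (row[1:] == CellState.INTERVENTION_MEASURED).all()

    def test_smallest_stepped_wedge_treatment_rows(self):
        d = build_complete_design(2, 3)
        treat = d.treated.astype(int)
        assert treat.tolist() == [[0, 1, 1], [0, 0, 1]]

    def test_lower_triangular_pattern_any_size(self):
        for k in (2, 3, 4, 7):
            d = build_complete_design(k)
            expected = (np.arange(k + 1)[None, :] >= np.arange(1, k + 1)[:, None]).astype(int)
            assert np.array_equal(d.treated.astype(int), expected)

    def test_total_measurements_weighted_by_allocation(self):
        d = build_complete_design(5, allocation=3)
        m = compute_design_metrics(d)
        assert m.total_measurements == 90

    @pytest.mark.parametrize("bad", [0, -2])
    def test_nonpositive_dimensions_rejected(self, bad):
        with pytest.raises(ValueError):
            build_complete_design(bad)


class TestTreatmentIndicator:
    def test_complete_design_cells(self):
        d = build_complete_design(5)
        assert treatment_indicator(d, 0, 0) == 0
        assert treatment_indicator(d, 0, 1) == 1

    def test_implementation_and_unmeasured_flagged(self):
        designs = enumerate_incomplete_designs(ConstraintSet())
        d = designs[0]
        impl = np.flatnonzero(d.cells[0] == CellState.IMPLEMENTATION)[0]
        assert treatment_indicator(d, 0, impl) == IMPLEMENTATION
        unm = np.flatnonzero(~d.measured[0] & (d.cells[0] != CellState.IMPLEMENTATION))
        assert treatment_indicator(d, 0, unm[0]) == UNOBSERVED

    def test_out_of_range_rejected(self):
        d = build_complete_design(3)
        with pytest.raises(IndexError):
            treatment_indicator(d, 3, 0)
        with pytest.raises(IndexError):
            treatment_indicator(d, 0, 4)


class TestEnumeration:
    def test_default_constraints_yield_256(self):
        designs = enumerate_incomplete_designs(ConstraintSet())
        assert len(designs) == 256

    def test_enumeration_idempotent_and_ordered(self):
        a = [d.encode() for d in enumerate_incomplete_designs(ConstraintSet())]
        b = [d.encode() for d in enumerate_incomplete_designs(ConstraintSet())]
        assert a == b
        assert len(set(a)) == len(a)  # no duplicates

    def test_every_enumerated_design_valid(self):
        for d in enumerate_incomplete_designs(ConstraintSet()):
            d.validate()
            # exactly one baseline + 3 in-year measurements per sequence
            assert (d.measured.sum(axis=1) == 4).all()
            # post-implementation term always measured
            for s in range(d.n_sequences):
                impl = np.flatnonzero(d.cells[s] == CellState.IMPLEMENTATION)
                assert d.measured[s, impl[0] + 1]

    def test_consecutive_rule_holds(self):
        for d in enumerate_incomplete_designs(ConstraintSet()):
            for s in range(d.n_sequences):
                runs = 0
                for p in range(1, d.n_periods):  # in-year terms only
                    runs = runs + 1 if d.measured[s, p] else 0
                    assert runs <= 2

    def test_adding_constraint_never_increases_count(self):
        relaxed = ConstraintSet(spread_blocks=None, max_consecutive=None)
        mid = ConstraintSet(spread_blocks=None)
        full = ConstraintSet()
        n_relaxed = len(enumerate_incomplete_designs(relaxed))
        n_mid = len(enumerate_incomplete_designs(mid))
        n_full = len(enumerate_incomplete_designs(full))
        assert n_relaxed >= n_mid >= n_full

    def test_relaxed_schedules_lazy_iteration(self):
        # any 3 of 6 in-year terms with no other rules: 20 schedules per
        # sequence, 20^5 configurations, consumed lazily
        cs = ConstraintSet(
            implementation_terms=None,
            require_post_implementation=False,
            max_consecutive=None,
            spread_blocks=None,
        )
        it = iter_incomplete_designs(cs)
        first = list(itertools.islice(it, 50))
        assert len(first) == 50
        # per-sequence count is C(6,3) = 20
        from swedge.design import ConstraintReport, _sequence_schedules

        report = ConstraintReport({}, {}, [])
        assert len(_sequence_schedules(cs, 0, report)) == 20

    def test_infeasible_constraints_reported(self):
        cs = ConstraintSet(measurements_per_year=7, spread_blocks=None)
        designs, report = enumerate_incomplete_designs(cs, return_report=True)
        assert designs == []
        assert not report.feasible
        assert report.blocking_rules()


class TestMetrics:
    def test_complete_design_measures_everywhere(self):
        d = build_complete_design(5, allocation=3)
        m = compute_design_metrics(d)
        assert (m.measurements_per_period == 15).all()

    def test_balance_counts_by_condition(self):
        d = build_complete_design(2, 3, allocation=2)
        m = compute_design_metrics(d)
        # period 0: both sequences control; period 2: both intervention
        assert m.control_intervention_balance[0] == (4, 0)
        assert m.control_intervention_balance[2] == (0, 4)
        assert m.control_intervention_balance[1] == (2, 2)

    def test_incomplete_design_span_and_runs(self):
        d = enumerate_incomplete_designs(ConstraintSet(), allocation=3)[0]
        m = compute_design_metrics(d)
        assert m.coverage_span[0] == 0
        assert m.total_measurements == 4 * 5 * 3
        assert (m.max_consecutive_measurements <= 2).all()


class TestCsvRoundTrip:
    def test_round_trip_bit_exact(self, tmp_path):
        for d in [
            build_complete_design(5, allocation=3),
            enumerate_incomplete_designs(ConstraintSet(), allocation=3)[17],
        ]:
            path = tmp_path / "d.csv"
            write_design_csv(d, path)
            first = path.read_bytes()
            d2 = read_design_csv(path)
            assert d2.encode() == d.encode()
            assert np.array_equal(d2.allocation, d.allocation)
            assert d2.period_labels == d.period_labels
            assert d2.baseline_period == d.baseline_period
            write_design_csv(d2, path)
            assert path.read_bytes() == first


class TestValidation:
    def test_non_monotone_treatment_rejected(self):
        d = build_complete_design(3)
        d.cells[0, 3] = CellState.CONTROL_MEASURED
        with pytest.raises(ValueError, match="monotone|control state"):
            d.validate()

    def test_design_without_control_measurements_rejected(self):
        d = build_complete_design(2, 3)
        d.cells[d.cells == CellState.CONTROL_MEASURED] = CellState.CONTROL_UNMEASURED
        with pytest.raises(ValueError, match="control"):
            d.validate()


class TestRoundTripProperty:
    """CSV serialisation is exact for arbitrary enumerated designs."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(index=st.integers(0, 255), alloc=st.integers(1, 9))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_any_enumerated_design_round_trips(self, tmp_path_factory, index, alloc):
        d = enumerate_incomplete_designs(ConstraintSet(), allocation=alloc)[index]
        path = tmp_path_factory.mktemp("designs") / "d.csv"
        write_design_csv(d, path)
        d2 = read_design_csv(path)
        assert d2.encode() == d.encode()
        assert list(d2.allocation) == list(d.allocation)
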