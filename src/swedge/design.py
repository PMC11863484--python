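"""Stepped wedge design configurations: representation, enumeration, metrics.

A design is a sequence-by-period matrix of cell states.  Sequences are groups
of schools that cross from control to intervention together; periods are
measurement occasions (here, UK school terms, with an optional baseline
occasion at the end of the previous school year).  Incomplete designs leave
some cells unmeasured, e.g. during a one-term implementation period in which
the intervention is embedded before intervention-condition data collection.

Periods are 0-based.  For school-year designs period 0 is the baseline
occasion and periods 1..6 are Terms 1..6.  The baseline is separated from
Term 1 by the summer holiday, so it never counts towards consecutive-term
measurement burden.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "CellState",
    "PeriodLabel",
    "DesignConfiguration",
    "DesignMetrics",
    "ConstraintSet",
    "ConstraintReport",
    "build_complete_design",
    "enumerate_incomplete_designs",
    "iter_incomplete_designs",
    "compute_design_metrics",
    "treatment_indicator",
    "write_design_csv",
    "read_design_csv",
    "IMPLEMENTATION",
    "UNOBSERVED",
]


class CellState(IntEnum):
    """State of one sequence-period cell."""

    CONTROL_MEASURED = 0
    CONTROL_UNMEASURED = 1
    IMPLEMENTATION = 2
    INTERVENTION_MEASURED = 3
    INTERVENTION_UNMEASURED = 4


#: single-character codes used in the CSV dialect
STATE_CODES = {
    CellState.CONTROL_MEASURED: "C",
    CellState.CONTROL_UNMEASURED: "c",
    CellState.IMPLEMENTATION: "X",
    CellState.INTERVENTION_MEASURED: "I",
    CellState.INTERVENTION_UNMEASURED: "i",
}
CODE_STATES = {v: k for k, v in STATE_CODES.items()}

MEASURED_STATES = (CellState.CONTROL_MEASURED, CellState.INTERVENTION_MEASURED)

# sentinels returned by treatment_indicator for non-outcome cells
IMPLEMENTATION = "implementation"
UNOBSERVED = "unobserved"


@dataclass(frozen=True)
class PeriodLabel:
    """Calendar position of a measurement period.

    Parameters
    ----------
    term : int
        School-term index (0 for the baseline occasion, 1..6 for Terms 1-6).
    months : float
        Mid-period time in months since the start of the school year
        (September = 0); the baseline occasion is negative.
    month_of_year : float
        Mid-period calendar month on a cyclic 12-month axis (January = 1),
        used to evaluate seasonal trends.
    """

    term: int
    months: float
    month_of_year: float


# default calendar: baseline in June of the previous school year, then the
# mid-term months of Terms 1-6 (Oct, late Nov, late Jan, Mar, late Apr, Jun)
_SCHOOL_YEAR_LABELS = [
    PeriodLabel(0, -3.0, 6.0),
    PeriodLabel(1, 1.0, 10.0),
    PeriodLabel(2, 2.5, 11.5),
    PeriodLabel(3, 4.5, 1.5),
    PeriodLabel(4, 6.0, 3.0),
    PeriodLabel(5, 7.5, 4.5),
    PeriodLabel(6, 9.0, 6.0),
]


def default_period_labels(n_periods: int, baseline: bool = True) -> list[PeriodLabel]:
    """Default calendar labels for a design with ``n_periods`` periods.

    Designs longer than one school year continue at 1.5-month term spacing
    into subsequent years.
    """
    base = _SCHOOL_YEAR_LABELS if baseline else _SCHOOL_YEAR_LABELS[1:]
    labels = list(base[:n_periods])
    term, months = len(base) - 1, base[-1].months
    while len(labels) < n_periods:
        term += 1
        months += 1.5
        labels.append(PeriodLabel(term, months, (months + 9.0) % 12.0))
    return labels


@dataclass
class DesignConfiguration:
    """A stepped wedge design: cell-state matrix plus school allocation."""

    cells: np.ndarray  # (n_sequences, n_periods) of CellState values
    allocation: np.ndarray  # schools per sequence
    period_labels: list[PeriodLabel] = field(default_factory=list)
    baseline_period: int | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int8)
        self.allocation = np.asarray(self.allocation, dtype=np.int64)
        if self.cells.ndim != 2:
            raise ValueError("cells must be a 2-d matrix")
        if self.allocation.shape != (self.cells.shape[0],):
            raise ValueError("allocation must have one entry per sequence")
        if not self.period_labels:
            self.period_labels = default_period_labels(
                self.cells.shape[1], baseline=self.baseline_period is not None
            )
        if len(self.period_labels) != self.cells.shape[1]:
            raise ValueError("period_labels must have one entry per period")

    # -- basic geometry -------------------------------------------------
    @property
    def n_sequences(self) -> int:
        return self.cells.shape[0]

    @property
    def n_periods(self) -> int:
        return self.cells.shape[1]

    @property
    def total_schools(self) -> int:
        return int(self.allocation.sum())

    @property
    def measured(self) -> np.ndarray:
        """Boolean (sequence, period) mask of measured cells."""
        return np.isin(self.cells, MEASURED_STATES)

    @property
    def treated(self) -> np.ndarray:
        """Boolean mask: cell is under intervention (post-implementation)."""
        return np.isin(
            self.cells,
            (CellState.INTERVENTION_MEASURED, CellState.INTERVENTION_UNMEASURED),
        )

    def measured_periods(self, sequence: int) -> np.ndarray:
        return np.flatnonzero(self.measured[sequence])

    # -- identity -------------------------------------------------------
    def encode(self) -> str:
        """Compact row-wise state string, e.g. ``'CcXIcI|CCxII..'``."""
        return "|".join(
            "".join(STATE_CODES[CellState(v)] for v in row) for row in self.cells
        )

    @property
    def design_id(self) -> str:
        return self.name or self.encode()

    def seed_key(self) -> int:
        """Stable 32-bit key for seeding, derived from the cell pattern."""
        return zlib.crc32(self.encode().encode())

    def with_allocation(self, allocation: Sequence[int]) -> "DesignConfiguration":
        return replace(self, allocation=np.asarray(allocation))

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        """Check all structural invariants; raise ``ValueError`` on failure."""
        for s in range(self.n_sequences):
            row = self.cells[s]
            impl = np.flatnonzero(row == CellState.IMPLEMENTATION)
            if impl.size:
                if not np.array_equal(impl, np.arange(impl[0], impl[-1] + 1)):
                    raise ValueError(f"sequence {s}: implementation block not contiguous")
            treated = self.treated[s].astype(int)
            if np.any(np.diff(treated) < 0):
                raise ValueError(f"sequence {s}: treatment not monotone over time")
            ctrl = np.flatnonzero(
                np.isin(row, (CellState.CONTROL_MEASURED, CellState.CONTROL_UNMEASURED))
            )
            if impl.size and ctrl.size and ctrl.max() > impl.min():
                raise ValueError(f"sequence {s}: control state after implementation")
        meas, treat = self.measured, self.treated
        if not np.any(meas & ~treat):
            raise ValueError("design has no measured control cell")
        if not np.any(meas & treat):
            raise ValueError("design has no measured intervention cell")
        if np.any(self.allocation <= 0):
            raise ValueError("allocation entries must be positive")


def treatment_indicator(design: DesignConfiguration, sequence: int, period: int):
    """Treatment status of one cell: 0, 1, 'implementation' or 'unobserved'.

    Returns 1 only for measured post-implementation (intervention) cells and
    0 for measured control cells, so the data generator never samples
    outcomes during implementation or in unmeasured cells.
    """
    if not (0 <= sequence < design.n_sequences and 0 <= period < design.n_periods):
        raise IndexError(f"cell ({sequence}, {period}) out of range")
    state = CellState(design.cells[sequence, period])
    if state == CellState.IMPLEMENTATION:
        return IMPLEMENTATION
    if state in (CellState.CONTROL_UNMEASURED, CellState.INTERVENTION_UNMEASURED):
        return UNOBSERVED
    return int(state == CellState.INTERVENTION_MEASURED)


def build_complete_design(
    n_sequences: int,
    n_periods: int | None = None,
    allocation: Sequence[int] | int = 1,
) -> DesignConfiguration:
    """Canonical complete stepped wedge: all cells measured, no implementation.

    Sequence ``s`` (0-based) switches to intervention at period ``s + 1``,
    giving the textbook lower-triangular treatment pattern for
    ``n_periods = n_sequences + 1``.
    """
    if n_sequences < 1:
        raise ValueError("n_sequences must be positive")
    if n_periods is None:
        n_periods = n_sequences + 1
    if n_periods < 2:
        raise ValueError("n_periods must be at least 2")
    cells = np.full((n_sequences, n_periods), CellState.CONTROL_MEASURED, dtype=np.int8)
    for s in range(n_sequences):
        cells[s, s + 1 :] = CellState.INTERVENTION_MEASURED
    if np.isscalar(allocation):
        allocation = [int(allocation)] * n_sequences
    return DesignConfiguration(
        cells=cells,
        allocation=np.asarray(allocation),
        period_labels=default_period_labels(n_periods, baseline=True),
        baseline_period=0,
        name=f"complete_{n_sequences}x{n_periods}",
    )


# ---------------------------------------------------------------------------
# enumeration of incomplete designs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConstraintSet:
    """Toggleable rules defining the candidate incomplete designs.

    The defaults encode the school-year study: five sequences implementing
    the intervention one term each in Terms 1-5, a baseline occasion common
    to all sequences, exactly three in-year measurements per sequence, a
    measurement in the term immediately after implementation, at most two
    measurements in consecutive terms, and measurements spread over the year
    (exactly one per third of the year: Terms 1-2, 3-4, 5-6).  With all
    defaults active the enumeration yields exactly 256 configurations; the
    spread rule is the calibrated reading, see docs/methods.md.
    """

    n_sequences: int = 5
    n_terms: int = 6
    implementation_terms: tuple[int, ...] | None = (1, 2, 3, 4, 5)
    baseline: bool = True
    measurements_per_year: int | None = 3
    require_post_implementation: bool = True
    max_consecutive: int | None = 2
    spread_blocks: tuple[tuple[int, ...], ...] | None = ((1, 2), (3, 4), (5, 6))

    def __post_init__(self) -> None:
        if self.implementation_terms is not None and len(self.implementation_terms) != self.n_sequences:
            raise ValueError("need one implementation term per sequence")


@dataclass
class ConstraintReport:
    """Per-rule elimination bookkeeping from a schedule enumeration."""

    candidates: dict[int, int]
    eliminated: dict[int, dict[str, int]]
    infeasible_sequences: list[int]

    @property
    def feasible(self) -> bool:
        return not self.infeasible_sequences

    def blocking_rules(self) -> dict[int, str]:
        """For each infeasible sequence, the rule that removed the last candidates."""
        out = {}
        for s in self.infeasible_sequences:
            rules = self.eliminated[s]
            out[s] = max(rules, key=lambda r: (rules[r] > 0, r)) if rules else "size"
        return out


def _max_run(terms: frozenset[int], n_terms: int) -> int:
    run = best = 0
    for t in range(1, n_terms + 1):
        run = run + 1 if t in terms else 0
        best = max(best, run)
    return best


def _sequence_schedules(
    constraints: ConstraintSet, s: int, report: ConstraintReport
) -> list[frozenset[int]]:
    """Valid in-year measurement-term sets for sequence ``s``, sorted."""
    c = constraints
    impl = c.implementation_terms[s] if c.implementation_terms else None
    terms = [t for t in range(1, c.n_terms + 1) if t != impl]
    sizes = (
        [c.measurements_per_year]
        if c.measurements_per_year is not None
        else range(1, len(terms) + 1)
    )
    cands = [
        frozenset(m) for k in sizes for m in itertools.combinations(terms, k)
    ]
    report.candidates[s] = len(cands)
    elim = report.eliminated.setdefault(s, {})

    def apply(name: str, pred) -> None:
        nonlocal cands
        kept = [m for m in cands if pred(m)]
        elim[name] = elim.get(name, 0) + len(cands) - len(kept)
        cands = kept

    if c.require_post_implementation and impl is not None:
        post = impl + 1
        if post <= c.n_terms:
            apply("post_implementation", lambda m: post in m)
    if c.max_consecutive is not None:
        apply("max_consecutive", lambda m: _max_run(m, c.n_terms) <= c.max_consecutive)
    if c.spread_blocks is not None:
        blocks = c.spread_blocks
        apply(
            "spread_blocks",
            lambda m: all(sum(1 for t in m if t in b) == 1 for b in blocks),
        )
    if not cands:
        report.infeasible_sequences.append(s)
    return sorted(cands, key=lambda m: tuple(sorted(m)))


def _assemble(
    constraints: ConstraintSet,
    schedules: tuple[frozenset[int], ...],
    allocation: np.ndarray,
) -> DesignConfiguration:
    c = constraints
    n_periods = c.n_terms + (1 if c.baseline else 0)
    off = 1 if c.baseline else 0
    cells = np.empty((c.n_sequences, n_periods), dtype=np.int8)
    for s, meas in enumerate(schedules):
        impl = c.implementation_terms[s] if c.implementation_terms else c.n_terms + 1
        for t in range(1, c.n_terms + 1):
            if t < impl:
                state = CellState.CONTROL_MEASURED if t in meas else CellState.CONTROL_UNMEASURED
            elif t == impl:
                state = CellState.IMPLEMENTATION
            else:
                state = (
                    CellState.INTERVENTION_MEASURED
                    if t in meas
                    else CellState.INTERVENTION_UNMEASURED
                )
            cells[s, t - 1 + off] = state
        if c.baseline:
            cells[s, 0] = CellState.CONTROL_MEASURED
    return DesignConfiguration(
        cells=cells,
        allocation=allocation,
        period_labels=default_period_labels(n_periods, baseline=c.baseline),
        baseline_period=0 if c.baseline else None,
    )


def iter_incomplete_designs(
    constraints: ConstraintSet,
    allocation: Sequence[int] | int = 1,
) -> Iterator[DesignConfiguration]:
    """Lazily yield all designs satisfying ``constraints``.

    Output order is deterministic: lexicographic in the per-sequence
    measurement patterns (equivalently, in the encoded state string).
    """
    report = ConstraintReport({}, {}, [])
    per_seq = [
        _sequence_schedules(constraints, s, report)
        for s in range(constraints.n_sequences)
    ]
    if not report.feasible:
        return
    if np.isscalar(allocation):
        allocation = [int(allocation)] * constraints.n_sequences
    allocation = np.asarray(allocation)
    for combo in itertools.product(*per_seq):
        yield _assemble(constraints, combo, allocation)


def enumerate_incomplete_designs(
    constraints: ConstraintSet,
    allocation: Sequence[int] | int = 1,
    return_report: bool = False,
):
    """Enumerate all designs satisfying ``constraints`` (eager).

    Returns the (possibly empty) list of designs; with ``return_report=True``
    also returns a :class:`ConstraintReport` stating, per sequence, how many
    candidate schedules each rule eliminated — in particular which rule made
    the constraint set infeasible when the list is empty.
    """
    report = ConstraintReport({}, {}, [])
    per_seq = [
        _sequence_schedules(constraints, s, report)
        for s in range(constraints.n_sequences)
    ]
    if report.feasible:
        if np.isscalar(allocation):
            allocation = [int(allocation)] * constraints.n_sequences
        alloc = np.asarray(allocation)
        designs = [
            _assemble(constraints, combo, alloc)
            for combo in itertools.product(*per_seq)
        ]
    else:
        designs = []
    return (designs, report) if return_report else designs


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


@dataclass
class DesignMetrics:
    """Logistics-facing summaries of a design, weighted by school allocation."""

    measurements_per_period: np.ndarray  # schools measured, per period
    control_intervention_balance: list[tuple[int, int]]  # (control, intervention) schools
    coverage_span: tuple[int, int]  # first and last measured period
    max_consecutive_measurements: np.ndarray  # per sequence, over in-year terms
    total_measurements: int


def compute_design_metrics(design: DesignConfiguration) -> DesignMetrics:
    design.validate()
    meas, treat = design.measured, design.treated
    alloc = design.allocation
    per_period = (meas * alloc[:, None]).sum(axis=0)
    balance = [
        (
            int((meas[:, p] & ~treat[:, p]) @ alloc),
            int((meas[:, p] & treat[:, p]) @ alloc),
        )
        for p in range(design.n_periods)
    ]
    measured_p = np.flatnonzero(per_period > 0)
    span = (int(measured_p[0]), int(measured_p[-1]))
    # consecutive-measurement burden counts school terms only: the baseline
    # occasion sits before the summer holiday and is not consecutive to Term 1
    start = design.baseline_period + 1 if design.baseline_period is not None else 0
    runs = np.zeros(design.n_sequences, dtype=int)
    for s in range(design.n_sequences):
        run = best = 0
        for p in range(start, design.n_periods):
            run = run + 1 if meas[s, p] else 0
            best = max(best, run)
        runs[s] = best
    return DesignMetrics(
        measurements_per_period=per_period,
        control_intervention_balance=balance,
        coverage_span=span,
        max_consecutive_measurements=runs,
        total_measurements=int((meas * alloc[:, None]).sum()),
    )


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------


def write_design_csv(design: DesignConfiguration, path) -> None:
    """Write the design as a human-diffable CSV matrix (round-trip exact)."""
    cols = ",".join(
        f"p{p}:t{lab.term}:m{lab.months:g}:y{lab.month_of_year:g}"
        for p, lab in enumerate(design.period_labels)
    )
    base = design.baseline_period if design.baseline_period is not None else ""
    lines = [f"sequence,schools,{cols}#baseline={base}"]
    for s in range(design.n_sequences):
        states = ",".join(STATE_CODES[CellState(v)] for v in design.cells[s])
        lines.append(f"{s},{design.allocation[s]},{states}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_design_csv(path) -> DesignConfiguration:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    header, rows = lines[0], lines[1:]
    head, _, base = header.partition("#baseline=")
    labels = []
    for col in head.split(",")[2:]:
        _, term, months, moy = col.split(":")
        labels.append(
            PeriodLabel(int(term[1:]), float(months[1:]), float(moy[1:]))
        )
    cells, alloc = [], []
    for row in rows:
        parts = row.split(",")
        alloc.append(int(parts[1]))
        cells.append([CODE_STATES[c] for c in parts[2:]])
    return DesignConfiguration(
        cells=np.array(cells, dtype=np.int8),
        allocation=np.array(alloc),
        period_labels=labels,
        baseline_period=int(base) if base != "" else None,
    )
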