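"""Pupil participation schemes: cross-sectional, closed cohort, open cohort.

The open cohort follows a closed-population scheme: schools have a fixed
eligible year group (e.g. 30 pupils) which is sampled repeatedly.  The scheme
is characterised by two rates:

* recruitment rate — probability an eligible pupil ever participates;
* retention rate — probability a participant at one measured occasion also
  participates at another.

Mechanism: the ever-participating subset is drawn once per school, then each
recruited pupil is present at each measured occasion independently with the
retention probability.  Independence gives both the stated marginal retention
(P(present at t+1 | present at t) = retention) and a mean per-occasion
participation of recruitment x retention among eligible pupils, reproducing
the reference rate mappings (58% -> 33%, 71% -> 50%, 82% -> 67%, 91% -> 83%
of eligible pupils per occasion) while keeping cluster sizes stable over time.

``sampling_mode='expected_counts'`` fixes the recruited-set size and the
per-occasion head count at rounded expectations (the "10/30 or 20/60"
framing); ``'binomial'`` draws both stochastically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignConfiguration

__all__ = ["CohortScheme", "churn_rate", "generate_membership", "design_membership"]

KINDS = ("cross_sectional", "closed", "open")


@dataclass(frozen=True)
class CohortScheme:
    """Participation rules for one school's pupils across measured occasions."""

    kind: str
    eligible_per_school: int
    recruitment_rate: float = 1.0
    retention_rate: float = 1.0
    sampling_mode: str = "expected_counts"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.eligible_per_school < 1:
            raise ValueError("eligible_per_school must be at least 1")
        for name in ("recruitment_rate", "retention_rate"):
            r = getattr(self, name)
            if not 0 < r <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {r}")
        if self.sampling_mode not in ("expected_counts", "binomial"):
            raise ValueError(f"unknown sampling_mode {self.sampling_mode!r}")
        if self.kind == "closed" and self.retention_rate != 1.0:
            raise ValueError("closed cohorts have retention_rate = 1")

    @property
    def effective_retention(self) -> float:
        """Retention applied at each occasion (1 for closed cohorts)."""
        return self.retention_rate if self.kind == "open" else 1.0


def churn_rate(scheme: CohortScheme) -> float:
    """Attrition ('churn') rate: 1 - retention."""
    if scheme.kind == "cross_sectional":
        raise ValueError("churn is undefined for cross-sectional schemes")
    return 1.0 - scheme.effective_retention


def _draw_count(n: int, rate: float, mode: str, rng: np.random.Generator) -> int:
    if mode == "expected_counts":
        return int(np.round(n * rate))
    return int(rng.binomial(n, rate))


def generate_membership(
    scheme: CohortScheme,
    design: DesignConfiguration,
    sequence: int,
    school: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Membership table for one school allocated to ``sequence``.

    Returns a tidy frame with one row per (pupil, measured occasion) and a
    ``present`` flag; pupil ids are stable across occasions within the school
    and namespaced by school.
    """
    occasions = design.measured_periods(sequence)
    if occasions.size == 0:
        raise ValueError(f"sequence {sequence} has no measured occasion")
    E = scheme.eligible_per_school

    if scheme.kind == "cross_sectional":
        # fresh pupils each occasion; ids never repeat
        n_per = _draw_count(E, scheme.recruitment_rate, scheme.sampling_mode, rng)
        rows = []
        next_id = 0
        for occ in occasions:
            n = n_per if scheme.sampling_mode == "expected_counts" else _draw_count(
                E, scheme.recruitment_rate, "binomial", rng
            )
            for j in range(n):
                rows.append((school, next_id + j, int(occ), True))
            next_id += n
        return pd.DataFrame(rows, columns=["school", "pupil", "occasion", "present"])

    n_recruited = _draw_count(E, scheme.recruitment_rate, scheme.sampling_mode, rng)
    recruited = np.sort(rng.choice(E, size=n_recruited, replace=False))
    retention = scheme.effective_retention
    rows = []
    for occ in occasions:
        if retention >= 1.0:
            present = np.ones(n_recruited, dtype=bool)
        elif scheme.sampling_mode == "expected_counts":
            k = int(np.round(n_recruited * retention))
            present = np.zeros(n_recruited, dtype=bool)
            present[rng.choice(n_recruited, size=k, replace=False)] = True
        else:
            present = rng.random(n_recruited) < retention
        for j, pupil in enumerate(recruited):
            rows.append((school, int(pupil), int(occ), bool(present[j])))
    return pd.DataFrame(rows, columns=["school", "pupil", "occasion", "present"])


def design_membership(
    scheme: CohortScheme, design: DesignConfiguration, rng: np.random.Generator
) -> pd.DataFrame:
    """Membership for every school of the design, with global school ids.

    Schools are numbered consecutively through the allocation vector
    (sequence 0's schools first); each school consumes the generator in a
    fixed order so a single seed determines the table exactly.
    """
    frames = []
    school = 0
    for seq in range(design.n_sequences):
        for _ in range(int(design.allocation[seq])):
            tab = generate_membership(scheme, design, seq, school, rng)
            tab.insert(1, "sequence", seq)
            frames.append(tab)
            school += 1
    return pd.concat(frames, ignore_index=True)
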