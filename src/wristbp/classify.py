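"""Guideline-threshold hypertension classification and treatment-gap analysis.

Each reading is called hypertension-positive or -negative against a named
threshold set (CHEP home-monitoring confirmation 135/85 mmHg with an OR rule
across channels; SPRINT intensive systolic target 120 mmHg, systolic only).
Cross-tabulating a method's calls against a reference method's calls yields
the sensitivity, the *treatment gap* (the fraction of reference-hypertensive
measures the method calls normotensive — hypertensive patients a biased
device would leave untreated), and a one-tailed Fisher exact test of the
association.
"""
from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import BPReading, Channel

__all__ = [
    "ThresholdSet",
    "ConcordanceTable",
    "MethodThresholdReport",
    "CHEP",
    "SPRINT",
    "classify_reading",
    "classify_readings",
    "concordance",
    "treatment_gap",
    "fisher_exact_one_tailed",
    "method_comparison",
]


@dataclass(frozen=True)
class ThresholdSet:
    """Named hypertension thresholds; a missing diastolic threshold means the
    rule is systolic-only."""

    name: str
    systolic_threshold: float
    diastolic_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.systolic_threshold <= 0:
            raise ValueError("systolic threshold must be > 0")
        if self.diastolic_threshold is not None and self.diastolic_threshold <= 0:
            raise ValueError("diastolic threshold must be > 0")


#: Home-monitoring confirmation threshold: >=135 systolic OR >=85 diastolic.
CHEP = ThresholdSet("CHEP", 135.0, 85.0)
#: Intensive systolic target: >=120 systolic, no diastolic criterion.
SPRINT = ThresholdSet("SPRINT", 120.0, None)


def classify_reading(reading: BPReading, thresholds: ThresholdSet) -> bool:
    """Hypertensive call: systolic at/above threshold OR (if a diastolic
    threshold exists) diastolic at/above it.  Bounds are inclusive."""
    if reading.systolic >= thresholds.systolic_threshold:
        return True
    return (
        thresholds.diastolic_threshold is not None
        and reading.diastolic >= thresholds.diastolic_threshold
    )


def classify_readings(
    readings: Sequence[BPReading], thresholds: ThresholdSet
) -> np.ndarray:
    return np.array([classify_reading(r, thresholds) for r in readings], dtype=bool)


@dataclass(frozen=True)
class ConcordanceTable:
    """2x2 cross-tabulation of a method's calls against a reference.

    ``a``: reference+/method+, ``b``: reference+/method-,
    ``c``: reference-/method+, ``d``: reference-/method-.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be >= 0")
        if self.total == 0:
            raise ValueError("table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def sensitivity(self) -> float:
        """a / (a + b); NaN when there are no reference positives."""
        if self.a + self.b == 0:
            return float("nan")
        return self.a / (self.a + self.b)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def concordance(
    method_calls: Sequence[bool], reference_calls: Sequence[bool]
) -> ConcordanceTable:
    """Cross-tabulate aligned boolean call vectors."""
    m = np.asarray(method_calls, dtype=bool)
    r = np.asarray(reference_calls, dtype=bool)
    if m.shape != r.shape or m.ndim != 1:
        raise ValueError("call vectors must be equal-length 1-d sequences")
    if len(m) < 1:
        raise ValueError("call vectors must be non-empty")
    return ConcordanceTable(
        a=int(np.sum(r & m)),
        b=int(np.sum(r & ~m)),
        c=int(np.sum(~r & m)),
        d=int(np.sum(~r & ~m)),
    )


def treatment_gap(table: ConcordanceTable) -> float:
    """Fraction of reference-hypertensive measures the method calls negative.

    ``b / (a + b)`` — identically ``1 - sensitivity``.  Undefined (raises)
    without reference positives.
    """
    if table.a + table.b == 0:
        raise ValueError("treatment gap undefined without reference positives")
    return table.b / (table.a + table.b)


def fisher_exact_one_tailed(
    table: ConcordanceTable, alternative: str = "less"
) -> float:
    """One-tailed Fisher exact p for the a-cell with margins fixed.

    Under the null the a-cell is hypergeometric with the observed margins.
    ``alternative="less"`` sums the observed and more-extreme tables in the
    direction of the method *missing* reference positives (the treatment-gap
    concern; the default direction); ``"greater"`` takes the opposite tail
    (method concordant with / over-calling the reference positives).
    Degenerate margins (an empty row or column) give p = 1 by convention.
    """
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    m_total = table.total
    n_ref_pos = table.a + table.b
    n_meth_pos = table.a + table.c
    if alternative == "less":
        p = stats.hypergeom.cdf(table.a, m_total, n_ref_pos, n_meth_pos)
    else:
        p = stats.hypergeom.sf(table.a - 1, m_total, n_ref_pos, n_meth_pos)
    return float(min(1.0, max(p, 0.0)))


@dataclass(frozen=True)
class MethodThresholdReport:
    """One method's hypertension-call performance against the reference."""

    method: str
    threshold_set: str
    n: int
    positives_method: int
    positives_reference: int
    sensitivity: float
    treatment_gap: float
    fisher_p: float
    table: ConcordanceTable


def _patient_mean_readings(readings: Sequence[BPReading]) -> list[BPReading]:
    """Average each patient's readings into one per-patient pseudo-reading."""
    groups: dict[str, list[BPReading]] = defaultdict(list)
    for r in readings:
        groups[r.patient_id].append(r)
    out = []
    for pid in sorted(groups):
        rs = groups[pid]
        out.append(
            rs[0].replace(
                systolic=float(np.mean([r.systolic for r in rs])),
                diastolic=float(np.mean([r.diastolic for r in rs])),
                sd_systolic=None,
                sd_diastolic=None,
                order_index=0,
            )
        )
    return out


def method_comparison(
    readings_by_method: Mapping[str, Sequence[BPReading]],
    reference_method: str,
    threshold_sets: Sequence[ThresholdSet] = (CHEP, SPRINT),
    *,
    by: str = "measurement",
    alternative: str = "less",
) -> list[MethodThresholdReport]:
    """Classify every method against the reference under each threshold set.

    The readings of all methods must be aligned measurement-for-measurement
    (same patients and order indices — e.g. simultaneous or derived
    readings).  ``by="patient"`` first averages each patient's readings per
    method and classifies the per-patient means instead of individual
    measures; both groupings are meaningful and the choice is reported, not
    hidden.
    """
    if reference_method not in readings_by_method:
        raise ValueError(f"reference method {reference_method!r} absent")
    if by not in ("measurement", "patient"):
        raise ValueError("by must be 'measurement' or 'patient'")

    def prepared(method: str) -> list[BPReading]:
        rs = sorted(
            readings_by_method[method], key=lambda r: (r.patient_id, r.order_index)
        )
        return _patient_mean_readings(rs) if by == "patient" else rs

    ref_readings = prepared(reference_method)
    ref_keys = [(r.patient_id, r.order_index) for r in ref_readings]
    reports: list[MethodThresholdReport] = []
    for ts in threshold_sets:
        ref_calls = classify_readings(ref_readings, ts)
        for method in readings_by_method:
            if method == reference_method:
                continue
            rs = prepared(method)
            keys = [(r.patient_id, r.order_index) for r in rs]
            if keys != ref_keys:
                raise ValueError(
                    f"readings of {method!r} are not aligned with the reference"
                )
            calls = classify_readings(rs, ts)
            table = concordance(calls, ref_calls)
            gap = float("nan") if table.a + table.b == 0 else treatment_gap(table)
            reports.append(
                MethodThresholdReport(
                    method=method,
                    threshold_set=ts.name,
                    n=table.total,
                    positives_method=int(np.sum(calls)),
                    positives_reference=int(np.sum(ref_calls)),
                    sensitivity=table.sensitivity,
                    treatment_gap=gap,
                    fisher_p=fisher_exact_one_tailed(table, alternative),
                    table=table,
                )
            )
    return reports
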