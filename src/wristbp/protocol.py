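"""The two-day measurement protocol: eligibility, the bilateral arm-equality
screen, and assembly of simultaneous wrist/intra-arterial pairs.

The wrist cuff cannot sit on the arm being cannulated, so Day 1 screens every
candidate for bilateral blood-pressure equality (two blinded auscultatory
readings per arm; arms must agree within 10 mmHg systolic and 5 mmHg
diastolic, inclusive).  Day 2 yields ten readings per patient; the first two
wrist readings are conditioning only and are discarded, the remaining wrist
readings are paired with the intra-arterial reading recorded simultaneously.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import BPReading, Method, Stage
from .synth import PatientProfile

__all__ = [
    "ProtocolError",
    "EligibilityDecision",
    "ScreenDecision",
    "SimultaneousPair",
    "EXCLUSION_FLAGS",
    "eligibility_filter",
    "bilateral_equality_screen",
    "assemble_day2_pairs",
]


class ProtocolError(ValueError):
    """A session violates the protocol's structural preconditions."""


#: Recognized exclusion indicators (history/condition flags).
EXCLUSION_FLAGS = frozenset(
    {
        "prior_pci",
        "prior_cabg",
        "aortic_aneurysm",
        "peripheral_vascular_disease",
        "aortic_stenosis",
        "arrhythmia",
        "tremor",
        "carotid_bruit",
    }
)


@dataclass(frozen=True)
class EligibilityDecision:
    patient_id: str
    eligible: bool
    reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.eligible != (len(self.reasons) == 0):
            raise ValueError("eligible must hold exactly when reasons is empty")


def eligibility_filter(
    profile: PatientProfile,
    flags: Iterable[str] = (),
    *,
    min_age: float = 19.0,
    wrist_range: tuple[float, float] = (13.5, 23.0),
) -> EligibilityDecision:
    """Apply the inclusion/exclusion rules to one candidate.

    Ineligible if younger than ``min_age`` years, if the wrist circumference
    falls outside ``wrist_range`` (inclusive — the device's admissible cuff
    range, 13.5-23 cm), or if any exclusion flag is set.  Each violated rule
    contributes one reason identifier.
    """
    reasons: list[str] = []
    if profile.age < min_age:
        reasons.append("age")
    lo, hi = wrist_range
    if not lo <= profile.wrist_circumference <= hi:
        reasons.append("wrist_circumference")
    for flag in flags:
        if flag not in EXCLUSION_FLAGS:
            raise ValueError(f"unknown exclusion flag {flag!r}")
        reasons.append(flag)
    return EligibilityDecision(profile.patient_id, not reasons, tuple(reasons))


@dataclass(frozen=True)
class ScreenDecision:
    """Bilateral equality screen outcome with per-channel arm differences."""

    patient_id: str
    passed: bool
    delta_systolic: float  # left minus right, arm means, mmHg
    delta_diastolic: float

    @property
    def reasons(self) -> tuple[str, ...]:
        out = []
        if not self.passed:
            # recorded for the screening report; bounds are the screen's own
            if abs(self.delta_systolic) > 10.0:
                out.append("systolic")
            if abs(self.delta_diastolic) > 5.0:
                out.append("diastolic")
        return tuple(out)


def bilateral_equality_screen(
    left: Sequence[BPReading],
    right: Sequence[BPReading],
    *,
    systolic_limit: float = 10.0,
    diastolic_limit: float = 5.0,
) -> ScreenDecision:
    """Compare per-arm mean pressures between arms.

    Each arm contributes two auscultatory readings (one per observer); the
    screen passes iff the arm-mean differences satisfy ``|d_sys| <= 10`` and
    ``|d_dia| <= 5`` mmHg (closed bounds: "within +/-X" read inclusively).
    The observers' readings are averaged per arm before comparison, mirroring
    the double-observer intent of the screen.
    """
    if len(left) != 2 or len(right) != 2:
        raise ProtocolError("bilateral screen needs exactly 2 readings per arm")
    ids = {r.patient_id for r in list(left) + list(right)}
    if len(ids) != 1:
        raise ProtocolError("screen readings must belong to one patient")
    d_sys = float(np.mean([r.systolic for r in left]) - np.mean([r.systolic for r in right]))
    d_dia = float(np.mean([r.diastolic for r in left]) - np.mean([r.diastolic for r in right]))
    passed = abs(d_sys) <= systolic_limit and abs(d_dia) <= diastolic_limit
    return ScreenDecision(ids.pop(), passed, d_sys, d_dia)


@dataclass(frozen=True)
class SimultaneousPair:
    """A wrist reading and the intra-arterial reading recorded with it."""

    patient_id: str
    wrist: BPReading
    reference: BPReading
    stage: Stage

    def __post_init__(self) -> None:
        if self.wrist.patient_id != self.patient_id or self.reference.patient_id != self.patient_id:
            raise ValueError("pair members must share the patient id")
        if self.wrist.stage is not self.stage or self.reference.stage is not self.stage:
            raise ValueError("pair members must share the stage")
        if self.wrist.method is not Method.WRIST_CUFF:
            raise ValueError("wrist member must be a wrist_cuff reading")
        if self.reference.method not in (Method.INTRA_RADIAL, Method.INTRA_AORTIC):
            raise ValueError("reference member must be intra-arterial")


def _stage_pairs(
    session: Sequence[BPReading],
    stage: Stage,
    ref_method: Method,
    n_expected: int,
) -> list[SimultaneousPair]:
    wrist = sorted(
        (r for r in session if r.stage is stage and r.method is Method.WRIST_CUFF),
        key=lambda r: r.order_index,
    )
    refs = sorted(
        (r for r in session if r.stage is stage and r.method is ref_method),
        key=lambda r: r.order_index,
    )
    if len(wrist) != n_expected or len(refs) != n_expected:
        raise ProtocolError(
            f"incomplete stage {stage.value}: expected {n_expected} wrist and "
            f"{n_expected} {ref_method.value} readings, "
            f"got {len(wrist)} and {len(refs)}"
        )
    if [r.order_index for r in wrist] != [r.order_index for r in refs]:
        raise ProtocolError(f"mismatched order indices in stage {stage.value}")
    return [
        SimultaneousPair(w.patient_id, w, r, stage) for w, r in zip(wrist, refs)
    ]


def assemble_day2_pairs(
    session: Sequence[BPReading],
    *,
    n_pairs_per_site: int = 2,
    n_conditioning: int = 2,
) -> tuple[list[SimultaneousPair], list[SimultaneousPair]]:
    """Split one patient's Day-2 session into (radial pairs, aortic pairs).

    Conditioning wrist readings are checked for presence and then discarded —
    they were taken for patient conditioning only and are never analysed.
    Within each simultaneous stage, wrist and reference readings are paired
    by order index (the k-th wrist reading was recorded while the k-th
    intra-arterial reading was being taken).
    """
    session = list(session)
    ids = {r.patient_id for r in session}
    if len(ids) > 1:
        raise ProtocolError("session must contain a single patient's readings")
    conditioning = [
        r for r in session
        if r.stage is Stage.CONDITIONING and r.method is Method.WRIST_CUFF
    ]
    if len(conditioning) != n_conditioning:
        raise ProtocolError(
            f"expected {n_conditioning} conditioning readings, got {len(conditioning)}"
        )
    radial = _stage_pairs(session, Stage.RADIAL_SIMULTANEOUS, Method.INTRA_RADIAL, n_pairs_per_site)
    aortic = _stage_pairs(session, Stage.AORTIC_SIMULTANEOUS, Method.INTRA_AORTIC, n_pairs_per_site)
    return radial, aortic
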