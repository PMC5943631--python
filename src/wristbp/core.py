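"""Shared domain types for blood-pressure readings.

A :class:`BPReading` is one blood-pressure measurement: which method produced
it (wrist cuff, upper-arm cuff, auscultation, or an intra-arterial catheter at
the radial artery or ascending aorta), which arm it was taken on, the systolic
and diastolic pressures in mmHg, an optional per-reading standard deviation
(the wrist device reports one for every measure), the protocol stage it
belongs to, and its order within that stage.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace


class Method(str, enum.Enum):
    """How a pressure was obtained."""

    WRIST_CUFF = "wrist_cuff"
    UPPER_ARM_OSCILLOMETRIC = "upper_arm_oscillometric"
    UPPER_ARM_AUSCULTATORY = "upper_arm_auscultatory"
    INTRA_RADIAL = "intra_radial"
    INTRA_AORTIC = "intra_aortic"


class Arm(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    NONE = "none"


class Stage(str, enum.Enum):
    """Protocol stage a reading belongs to."""

    DAY1_BASELINE = "day1_baseline"
    CONDITIONING = "conditioning"
    RADIAL_SIMULTANEOUS = "radial_simultaneous"
    AORTIC_SIMULTANEOUS = "aortic_simultaneous"
    INDEPENDENT = "independent"


class Channel(str, enum.Enum):
    SYSTOLIC = "systolic"
    DIASTOLIC = "diastolic"


class Site(str, enum.Enum):
    """Arterial site of a beat-level pressure series."""

    AORTA = "aorta"
    RADIAL = "radial"


@dataclass(frozen=True)
class BPReading:
    """One blood-pressure measurement.

    Invariants: ``systolic > diastolic``; wrist-cuff readings carry per-reading
    SDs (the device reports a measure of uncertainty with every reading);
    ``order_index >= 0``.
    """

    patient_id: str
    method: Method
    arm: Arm
    stage: Stage
    order_index: int
    systolic: float
    diastolic: float
    sd_systolic: float | None = None
    sd_diastolic: float | None = None

    def __post_init__(self) -> None:
        if not self.systolic > self.diastolic:
            raise ValueError(
                f"systolic ({self.systolic}) must exceed diastolic "
                f"({self.diastolic}) for reading {self.patient_id!r}"
            )
        if self.order_index < 0:
            raise ValueError("order_index must be >= 0")
        if self.method is Method.WRIST_CUFF:
            if self.sd_systolic is None or self.sd_diastolic is None:
                raise ValueError("wrist_cuff readings must report per-reading SDs")
        for sd in (self.sd_systolic, self.sd_diastolic):
            if sd is not None and sd < 0:
                raise ValueError("per-reading SD must be >= 0")

    def pressure(self, channel: Channel) -> float:
        return self.systolic if channel is Channel.SYSTOLIC else self.diastolic

    def sd(self, channel: Channel) -> float | None:
        return self.sd_systolic if channel is Channel.SYSTOLIC else self.sd_diastolic

    def replace(self, **changes) -> "BPReading":
        return replace(self, **changes)


def round_half_away(x: float, base: float = 1.0) -> float:
    """Round ``x`` to the nearest multiple of ``base``, halves away from zero.

    Sphygmomanometer scales are graduated in 2-mmHg steps and observers record
    the nearest graduation; Python's banker's rounding would bias terminal
    digits, so the half-away convention is implemented explicitly.
    """
    if base <= 0:
        raise ValueError("base must be > 0")
    return math.copysign(math.floor(abs(x) / base + 0.5) * base, x)
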