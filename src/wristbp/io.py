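"""File I/O and run configuration.

All tabular artifacts are plain delimited text (comma-separated, header
row).  The readings table has exactly the columns ``patient_id, method, arm,
stage, order_index, systolic, diastolic, sd_systolic, sd_diastolic`` (empty
field = absent SD); beat series are ``time_s, systolic, diastolic``.
Calibration models and run summaries are JSON.  The run configuration is a
single YAML document with per-module sections.
"""
from __future__ import annotations

import csv
import dataclasses
import enum
import json
import typing
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .calibrate import CalibrationModel
from .classify import CHEP, SPRINT, MethodThresholdReport, ThresholdSet
from .core import Arm, BPReading, Channel, Method, Site, Stage
from .protocol import ScreenDecision
from .synth import (
    DEFAULT_DEVICE_MODEL,
    DEFAULT_UPPER_ARM_MODEL,
    BeatSeries,
    CohortConfig,
    DeviceModel,
    PatientProfile,
    ProtocolConfig,
)

__all__ = [
    "READINGS_COLUMNS",
    "ReadingsFormatError",
    "read_readings",
    "write_readings",
    "read_beat_series",
    "write_beat_series",
    "read_models",
    "write_models",
    "write_cohort",
    "write_screen_report",
    "write_method_report",
    "write_pairs_table",
    "RunConfig",
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "save_config",
]

READINGS_COLUMNS = [
    "patient_id",
    "method",
    "arm",
    "stage",
    "order_index",
    "systolic",
    "diastolic",
    "sd_systolic",
    "sd_diastolic",
]


class ReadingsFormatError(ValueError):
    """A readings table violates the declared format (message names the line)."""


def _fmt(x: float | None) -> str:
    # repr round-trips floats exactly, so write->read is the identity
    return "" if x is None else repr(float(x))


def write_readings(readings: Sequence[BPReading], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(READINGS_COLUMNS)
        for r in readings:
            w.writerow(
                [
                    r.patient_id,
                    r.method.value,
                    r.arm.value,
                    r.stage.value,
                    r.order_index,
                    _fmt(r.systolic),
                    _fmt(r.diastolic),
                    _fmt(r.sd_systolic),
                    _fmt(r.sd_diastolic),
                ]
            )


def read_readings(path) -> list[BPReading]:
    """Parse a readings table, enforcing row-level invariants.

    Rejected rows (missing columns, non-numeric pressures, systolic not above
    diastolic) raise :class:`ReadingsFormatError` naming the offending line.
    An empty-but-headered file parses to an empty list.
    """
    out: list[BPReading] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ReadingsFormatError(f"{path}: empty file (missing header)")
        if header != READINGS_COLUMNS:
            raise ReadingsFormatError(
                f"{path}: header mismatch: expected {READINGS_COLUMNS}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(READINGS_COLUMNS):
                raise ReadingsFormatError(
                    f"{path}, line {lineno}: expected {len(READINGS_COLUMNS)} fields"
                )
            try:
                reading = BPReading(
                    patient_id=row[0],
                    method=Method(row[1]),
                    arm=Arm(row[2]),
                    stage=Stage(row[3]),
                    order_index=int(row[4]),
                    systolic=float(row[5]),
                    diastolic=float(row[6]),
                    sd_systolic=float(row[7]) if row[7] != "" else None,
                    sd_diastolic=float(row[8]) if row[8] != "" else None,
                )
            except (ValueError, KeyError) as exc:
                raise ReadingsFormatError(f"{path}, line {lineno}: {exc}") from exc
            out.append(reading)
    return out


def write_beat_series(series: BeatSeries, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "systolic", "diastolic"])
        for t, s, d in zip(series.times, series.systolic, series.diastolic):
            w.writerow([_fmt(float(t)), _fmt(float(s)), _fmt(float(d))])


def read_beat_series(path, site: Site = Site.RADIAL) -> BeatSeries:
    times, sys_p, dia_p = [], [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != ["time_s", "systolic", "diastolic"]:
            raise ReadingsFormatError(f"{path}: unexpected beat-series header {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                times.append(float(row[0]))
                sys_p.append(float(row[1]))
                dia_p.append(float(row[2]))
            except (ValueError, IndexError) as exc:
                raise ReadingsFormatError(f"{path}, line {lineno}: {exc}") from exc
    return BeatSeries(site, times, sys_p, dia_p)


def write_models(models: Sequence[CalibrationModel], path) -> None:
    payload = [
        {
            "channel": m.channel.value,
            "intercept": m.intercept,
            "slope": m.slope,
            "reference_site": None if m.reference_site is None else m.reference_site.value,
            "n_training": m.n_training,
            "family": m.family,
        }
        for m in models
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_models(path) -> list[CalibrationModel]:
    payload = json.loads(Path(path).read_text())
    return [
        CalibrationModel(
            channel=Channel(m["channel"]),
            intercept=float(m["intercept"]),
            slope=float(m["slope"]),
            reference_site=None if m["reference_site"] is None else Site(m["reference_site"]),
            n_training=int(m["n_training"]),
            family=m.get("family", "affine"),
        )
        for m in payload
    ]


def write_cohort(cohort: Sequence[PatientProfile], path) -> None:
    cols = [f.name for f in dataclasses.fields(PatientProfile)]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for p in cohort:
            w.writerow([getattr(p, c) for c in cols])


def write_screen_report(decisions: Sequence[ScreenDecision], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "decision", "delta_systolic", "delta_diastolic", "reasons"])
        for d in decisions:
            w.writerow(
                [
                    d.patient_id,
                    "pass" if d.passed else "fail",
                    _fmt(d.delta_systolic),
                    _fmt(d.delta_diastolic),
                    ";".join(d.reasons),
                ]
            )


def write_method_report(rows: Sequence[MethodThresholdReport], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            [
                "method",
                "threshold_set",
                "n",
                "positives_method",
                "positives_reference",
                "sensitivity",
                "treatment_gap",
                "fisher_p",
            ]
        )
        for r in rows:
            w.writerow(
                [
                    r.method,
                    r.threshold_set,
                    r.n,
                    r.positives_method,
                    r.positives_reference,
                    _fmt(r.sensitivity),
                    _fmt(r.treatment_gap),
                    _fmt(r.fisher_p),
                ]
            )


def write_pairs_table(pairs, path) -> None:
    """Simultaneous pairs as a flat delimited table (one row per pair)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            [
                "patient_id",
                "stage",
                "order_index",
                "wrist_systolic",
                "wrist_diastolic",
                "wrist_sd_systolic",
                "wrist_sd_diastolic",
                "reference_method",
                "reference_systolic",
                "reference_diastolic",
            ]
        )
        for p in pairs:
            w.writerow(
                [
                    p.patient_id,
                    p.stage.value,
                    p.wrist.order_index,
                    _fmt(p.wrist.systolic),
                    _fmt(p.wrist.diastolic),
                    _fmt(p.wrist.sd_systolic),
                    _fmt(p.wrist.sd_diastolic),
                    p.reference.method.value,
                    _fmt(p.reference.systolic),
                    _fmt(p.reference.diastolic),
                ]
            )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Everything one end-to-end pipeline run needs, in one document."""

    seed: int = 0
    n_patients: int = 20
    cohort: CohortConfig = field(default_factory=CohortConfig)
    device: DeviceModel = field(default_factory=lambda: DEFAULT_DEVICE_MODEL)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    calibration_family: str = "affine"
    threshold_sets: tuple[ThresholdSet, ...] = (CHEP, SPRINT)
    upper_arm: DeviceModel = field(default_factory=lambda: DEFAULT_UPPER_ARM_MODEL)
    classification_by: str = "measurement"
    required_within_fraction: float = 1.0
    paired_test_kind: str = "t"
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.calibration_family not in ("affine", "offset"):
            raise ValueError("calibration_family must be 'affine' or 'offset'")
        if self.classification_by not in ("measurement", "patient"):
            raise ValueError("classification_by must be 'measurement' or 'patient'")
        if self.paired_test_kind not in ("t", "wilcoxon"):
            raise ValueError("paired_test_kind must be 't' or 'wilcoxon'")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def config_to_dict(config: RunConfig) -> dict:
    return _to_plain(config)


def _strip_optional(tp):
    origin = typing.get_origin(tp)
    if origin is typing.Union:
        args = [a for a in typing.get_args(tp) if a is not type(None)]
        if len(args) == 1:
            return args[0]
    return tp


def _build(tp, value):
    """Recursively construct a (possibly nested) config value from plain data."""
    if value is None:
        return None
    tp = _strip_optional(tp)
    origin = typing.get_origin(tp)
    if origin in (tuple, list):
        (item_tp, *rest) = typing.get_args(tp) or (typing.Any,)
        if rest and rest != [Ellipsis]:  # heterogeneous tuple
            return tuple(_build(t, v) for t, v in zip(typing.get_args(tp), value))
        built = [_build(item_tp, v) for v in value]
        return tuple(built) if origin is tuple else built
    if isinstance(tp, type) and issubclass(tp, enum.Enum):
        return tp(value)
    if dataclasses.is_dataclass(tp):
        if isinstance(value, tp):
            return value
        hints = typing.get_type_hints(tp)
        kwargs = {}
        for f in dataclasses.fields(tp):
            if f.name in value:
                kwargs[f.name] = _build(hints[f.name], value[f.name])
        return tp(**kwargs)
    if tp is float:
        return float(value)
    if tp is int:
        return int(value)
    return value


def config_from_dict(data: dict) -> RunConfig:
    """Build a :class:`RunConfig` from nested plain dicts (as parsed from
    YAML); nested sections validate against their modules' preconditions at
    construction time."""
    return _build(RunConfig, data)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))
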