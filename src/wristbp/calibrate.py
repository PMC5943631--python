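"""Jackknife leave-one-out calibration of device readings against
intra-arterial references.

The dataset of N simultaneous (device, reference) pairs is resampled N
times: at iteration i the i-th pair is the test set and the remaining N-1
pairs the training set; the training fit's coefficients are applied to the
held-out device value.  The held-out calibrated values feed the downstream
agreement analysis (honest out-of-sample evaluation); a *deployed* model,
fit on all N pairs, is retained for reuse on new readings.

The calibration family is per-channel affine (``reference ~ intercept +
slope * device``) by default — the minimal family expressing both an offset
and a gain error — with an offset-only alternative.  Systolic and diastolic
channels are calibrated independently, and either intra-arterial site
(radial artery or ascending aorta) can serve as the reference.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import BPReading, Channel, Method, Site

__all__ = [
    "CalibrationModel",
    "JackknifeResult",
    "fit_affine",
    "jackknife_calibrate",
    "apply_calibration",
    "pairs_to_arrays",
    "calibrate_pairs",
]

_FAMILIES = ("affine", "offset")


@dataclass(frozen=True)
class CalibrationModel:
    """Per-channel affine map from device output to reference pressure."""

    channel: Channel
    intercept: float
    slope: float
    reference_site: Site | None = None
    n_training: int = 0
    family: str = "affine"

    def __post_init__(self) -> None:
        if not np.isfinite(self.intercept) or not np.isfinite(self.slope):
            raise ValueError("coefficients must be finite")
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown calibration family {self.family!r}")

    def apply(self, device_value):
        """Calibrated pressure(s) for raw device output."""
        return self.intercept + self.slope * np.asarray(device_value, dtype=float)


def fit_affine(
    device: Sequence[float],
    reference: Sequence[float],
    channel: Channel,
    *,
    reference_site: Site | None = None,
    family: str = "affine",
) -> CalibrationModel:
    """Ordinary least squares of reference on device output.

    ``family="offset"`` constrains the slope to 1 and fits only the mean
    offset.  Raises on fewer than two pairs or (for the affine family) zero
    variance in the device values, where the slope is unidentifiable.
    """
    x = np.asarray(device, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("device and reference must be equal-length 1-d sequences")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs to fit a calibration")
    if family == "offset":
        return CalibrationModel(
            channel, float(np.mean(y - x)), 1.0, reference_site, len(x), family
        )
    if family != "affine":
        raise ValueError(f"unknown calibration family {family!r}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: device values have zero variance")
    res = stats.linregress(x, y)
    return CalibrationModel(
        channel, float(res.intercept), float(res.slope), reference_site, len(x), family
    )


@dataclass
class JackknifeResult:
    """Leave-one-out calibration of one channel against one reference site.

    ``models[i]`` was fit with pair i held out and produced ``calibrated[i]``
    from ``device[i]``; ``deployed`` is the full-data fit for reuse.
    """

    channel: Channel
    device: np.ndarray
    reference: np.ndarray
    calibrated: np.ndarray
    models: list[CalibrationModel]
    deployed: CalibrationModel

    def __post_init__(self) -> None:
        n = len(self.device)
        if not (len(self.reference) == len(self.calibrated) == len(self.models) == n):
            raise ValueError("inconsistent jackknife result lengths")

    @property
    def n(self) -> int:
        return len(self.device)

    @property
    def held_out_residuals(self) -> np.ndarray:
        """Calibrated-minus-reference differences, one per held-out pair."""
        return self.calibrated - self.reference


def jackknife_calibrate(
    device: Sequence[float],
    reference: Sequence[float],
    channel: Channel,
    *,
    reference_site: Site | None = None,
    family: str = "affine",
) -> JackknifeResult:
    """Leave-one-out iterative calibration of one channel.

    Needs N >= 3 pairs so each training set still supports an affine fit.
    """
    x = np.asarray(device, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("device and reference must be equal-length 1-d sequences")
    n = len(x)
    if n < 3:
        raise ValueError("jackknife calibration needs at least 3 pairs")
    models: list[CalibrationModel] = []
    calibrated = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        model = fit_affine(
            x[train], y[train], channel, reference_site=reference_site, family=family
        )
        models.append(model)
        calibrated[i] = model.apply(x[i])
    deployed = fit_affine(x, y, channel, reference_site=reference_site, family=family)
    return JackknifeResult(channel, x, y, calibrated, models, deployed)


def apply_calibration(
    reading: BPReading,
    systolic_model: CalibrationModel,
    diastolic_model: CalibrationModel,
) -> BPReading:
    """Calibrate one reading's pressures (and propagate its SDs).

    Per channel ``pressure -> intercept + slope * pressure``; a per-reading
    SD scales by the slope magnitude (an affine map leaves the spread scaled
    by the gain only).  Method and metadata are preserved.
    """
    if systolic_model.channel is not Channel.SYSTOLIC:
        raise ValueError("systolic_model must be a systolic-channel model")
    if diastolic_model.channel is not Channel.DIASTOLIC:
        raise ValueError("diastolic_model must be a diastolic-channel model")
    sd_s = reading.sd_systolic
    sd_d = reading.sd_diastolic
    return reading.replace(
        systolic=float(systolic_model.apply(reading.systolic)),
        diastolic=float(diastolic_model.apply(reading.diastolic)),
        sd_systolic=None if sd_s is None else abs(systolic_model.slope) * sd_s,
        sd_diastolic=None if sd_d is None else abs(diastolic_model.slope) * sd_d,
    )


def pairs_to_arrays(pairs, channel: Channel) -> tuple[np.ndarray, np.ndarray]:
    """(device values, reference values) for one channel from simultaneous pairs."""
    dev = np.array([p.wrist.pressure(channel) for p in pairs], dtype=float)
    ref = np.array([p.reference.pressure(channel) for p in pairs], dtype=float)
    return dev, ref


def calibrate_pairs(
    pairs,
    *,
    family: str = "affine",
) -> dict[Channel, JackknifeResult]:
    """Jackknife-calibrate both channels of a pooled set of simultaneous pairs.

    The reference site is inferred from the pairs' reference method and must
    be homogeneous (readings calibrated to the radial artery and to the
    ascending aorta are separate analyses).
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no pairs to calibrate")
    methods = {p.reference.method for p in pairs}
    if len(methods) != 1:
        raise ValueError("pairs mix reference sites; calibrate each site separately")
    site = Site.RADIAL if methods.pop() is Method.INTRA_RADIAL else Site.AORTA
    out: dict[Channel, JackknifeResult] = {}
    for channel in Channel:
        dev, ref = pairs_to_arrays(pairs, channel)
        out[channel] = jackknife_calibrate(
            dev, ref, channel, reference_site=site, family=family
        )
    return out
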