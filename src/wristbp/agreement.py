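"""Bland-Altman (Tukey mean-difference) agreement analysis.

For paired measurements (a_i, b_i) of the same quantity by two methods, the
analysis summarizes the differences d_i = a_i - b_i against the pair means
m_i = (a_i + b_i)/2.  Alongside the conventional signed statistics (mean
difference, SD, limits of agreement = mean +/- 1.96 SD), the *absolute* mean
difference E|d| with its own SD is always reported: device-validation work
often quotes this absolute family as "the bias", since with enough pairs a
signed mean difference can average to zero while individual readings remain
far off.  An a-priori validity rule (all pairs within 10 mmHg systolic /
5 mmHg diastolic) and pre-vs-post calibration improvement percentages
complete the module.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import Channel, round_half_away

__all__ = [
    "AgreementReport",
    "Improvement",
    "DEFAULT_VALIDITY_THRESHOLDS",
    "bland_altman",
    "paired_test",
    "validity_check",
    "improvement_metrics",
]

#: A-priori validity thresholds (mmHg): any two measures of the same pressure
#: should agree within 10 (systolic) / 5 (diastolic).
DEFAULT_VALIDITY_THRESHOLDS = {Channel.SYSTOLIC: 10.0, Channel.DIASTOLIC: 5.0}


@dataclass(frozen=True)
class AgreementReport:
    """Summary of one Bland-Altman comparison.

    ``signed_*`` is the conventional bias family; ``absolute_mean_difference``
    (with ``sd_absolute``) is the absolute family.  ``trend_slope`` is the
    least-squares slope of difference on pair mean (a nonzero value flags
    pressure-dependent disagreement).  Fields may be NaN on reports built
    from published summary statistics rather than raw pairs.
    """

    channel: Channel
    n: int
    signed_mean_difference: float
    absolute_mean_difference: float
    sd_signed: float
    sd_absolute: float
    limits_of_agreement: tuple[float, float]
    paired_p: float
    within_threshold_fraction: float
    threshold: float
    trend_slope: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        amd, smd = self.absolute_mean_difference, self.signed_mean_difference
        if not (math.isnan(amd) or math.isnan(smd)) and amd < abs(smd) - 1e-9:
            raise ValueError("absolute mean difference cannot be below |signed|")
        wtf = self.within_threshold_fraction
        if not math.isnan(wtf) and not 0.0 <= wtf <= 1.0:
            raise ValueError("within_threshold_fraction must lie in [0, 1]")

    @classmethod
    def from_summary(
        cls,
        channel: Channel,
        n: int,
        absolute_mean_difference: float,
        sd_absolute: float,
        **extra,
    ) -> "AgreementReport":
        """Report carrying published summary statistics only (rest NaN)."""
        nan = float("nan")
        values = dict(
            signed_mean_difference=nan,
            sd_signed=nan,
            limits_of_agreement=(nan, nan),
            paired_p=nan,
            within_threshold_fraction=nan,
            threshold=DEFAULT_VALIDITY_THRESHOLDS[channel],
            trend_slope=nan,
        )
        values.update(extra)
        return cls(
            channel=channel,
            n=n,
            absolute_mean_difference=absolute_mean_difference,
            sd_absolute=sd_absolute,
            **values,
        )


def paired_test(differences: Sequence[float], kind: str = "t") -> float:
    """Two-sided p-value for mean paired difference = 0.

    ``kind="t"`` is the paired two-sided t test (the conventional choice for
    quoted agreement P values); ``kind="wilcoxon"`` the signed-rank
    alternative.  Degenerate inputs follow the usual conventions: zero
    variance with zero mean gives p = 1 (no evidence of a shift), zero
    variance with nonzero mean gives the limiting p = 0.
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1 or len(d) < 2:
        raise ValueError("need at least 2 paired differences")
    if np.ptp(d) == 0:
        return 1.0 if d[0] == 0 else 0.0
    if kind == "t":
        return float(stats.ttest_1samp(d, 0.0).pvalue)
    if kind == "wilcoxon":
        if np.all(d == 0):  # pragma: no cover - caught by ptp above
            return 1.0
        return float(stats.wilcoxon(d).pvalue)
    raise ValueError(f"unknown test kind {kind!r}")


def bland_altman(
    a: Sequence[float],
    b: Sequence[float],
    channel: Channel,
    *,
    validity_threshold: float | None = None,
    test: str = "t",
) -> AgreementReport:
    """Bland-Altman comparison of method ``a`` against method ``b``.

    Differences are ``a - b``.  ``validity_threshold`` defaults to the
    a-priori 10/5 mmHg rule for the channel; the within-threshold comparison
    is inclusive (``|d| <= threshold`` counts as within).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-d sequences")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    threshold = (
        DEFAULT_VALIDITY_THRESHOLDS[channel]
        if validity_threshold is None
        else float(validity_threshold)
    )
    d = a - b
    m = (a + b) / 2.0
    abs_d = np.abs(d)
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    if np.ptp(m) > 0:
        trend = float(np.polyfit(m, d, 1)[0])
    else:
        trend = 0.0
    return AgreementReport(
        channel=channel,
        n=len(d),
        signed_mean_difference=mean_d,
        absolute_mean_difference=float(np.mean(abs_d)),
        sd_signed=sd_d,
        sd_absolute=float(np.std(abs_d, ddof=1)),
        limits_of_agreement=(mean_d - 1.96 * sd_d, mean_d + 1.96 * sd_d),
        paired_p=paired_test(d, kind=test),
        within_threshold_fraction=float(np.mean(abs_d <= threshold)),
        threshold=threshold,
        trend_slope=trend,
    )


def validity_check(report: AgreementReport, *, required_fraction: float = 1.0) -> bool:
    """Apply the a-priori validity rule to a report.

    Passes iff the fraction of pairs within the report's threshold reaches
    ``required_fraction`` (default 1.0: *any* two measures must agree within
    the threshold).  Comparison is inclusive.
    """
    if not 0.0 <= required_fraction <= 1.0:
        raise ValueError("required_fraction must lie in [0, 1]")
    if math.isnan(report.within_threshold_fraction):
        raise ValueError("report carries no within-threshold fraction")
    return report.within_threshold_fraction >= required_fraction


@dataclass(frozen=True)
class Improvement:
    """Pre-to-post calibration change in agreement, as percentages.

    ``accuracy_improvement`` is the relative drop in absolute mean
    difference, ``variability_reduction`` the relative drop in its SD.
    Unrounded values are primary; display rounding is half-away-from-zero to
    whole percent.
    """

    channel: Channel
    accuracy_improvement: float
    variability_reduction: float

    @property
    def accuracy_improvement_rounded(self) -> int:
        return int(round_half_away(self.accuracy_improvement))

    @property
    def variability_reduction_rounded(self) -> int:
        return int(round_half_away(self.variability_reduction))


def improvement_metrics(pre: AgreementReport, post: AgreementReport) -> Improvement:
    """Percent accuracy improvement and variability reduction, pre vs post.

    ``accuracy = 100 * (pre.AMD - post.AMD) / pre.AMD`` and analogously for
    the SD of absolute differences.  Both reports must describe the same
    channel and the pre-calibration values must be nonzero.
    """
    if pre.channel is not post.channel:
        raise ValueError("pre and post reports must share a channel")
    if not pre.absolute_mean_difference > 0:
        raise ValueError("pre-calibration absolute mean difference must be > 0")
    if not pre.sd_absolute > 0:
        raise ValueError("pre-calibration SD of absolute differences must be > 0")
    acc = 100.0 * (pre.absolute_mean_difference - post.absolute_mean_difference) / pre.absolute_mean_difference
    var = 100.0 * (pre.sd_absolute - post.sd_absolute) / pre.sd_absolute
    return Improvement(pre.channel, float(acc), float(var))
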