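"""Synthetic cohorts, beat-level pressure series, and device/observer readings.

No patient-level data accompany the study design this package analyses, so
everything downstream is exercised on simulated data with the statistical
structure the analysis assumes:

* a cohort whose demographics and central/peripheral pressures follow the
  published participant-characteristics table (moment-matched truncated
  normals, so sample means/SDs reproduce the configured values even though
  draws are restricted to the configured ranges);
* beat-to-beat intraphysiological variability as a stationary AR(1) process
  whose 4-minute swing is ~20 mmHg systolic / ~10 mmHg diastolic;
* systolic pressure augmentation between the ascending aorta and the radial
  artery (radial systolic runs ~12 mmHg above aortic in this population);
* a wrist-cuff device with an affine miscalibration and measurement noise
  that reports a per-reading SD, a documented stand-in for the proprietary
  oscillometric pipeline (an explicit envelope + fixed-ratio model is also
  provided);
* double-observer auscultatory readings rounded to the 2-mmHg scale;
* the full two-day measurement schedule plus an independent auscultatory
  comparison set (default 375 measurements across 97 participants).

All generators are pure functions of their inputs and a seed.
"""
from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .core import Arm, BPReading, Channel, Method, Site, Stage, round_half_away

__all__ = [
    "TruncatedNormalSpec",
    "CohortConfig",
    "PatientProfile",
    "BeatSeries",
    "DeviceModel",
    "ObserverModel",
    "ProtocolConfig",
    "StudyDataset",
    "CuffDeflation",
    "OscillometricEnvelope",
    "OscillometricEstimate",
    "DEFAULT_DEVICE_MODEL",
    "IDENTITY_DEVICE_MODEL",
    "DEFAULT_UPPER_ARM_MODEL",
    "AR1_RANGE_FACTOR_25",
    "simulate_cohort",
    "simulate_beat_series",
    "oscillometric_envelope",
    "fixed_ratio_estimate",
    "device_reading",
    "auscultatory_reading",
    "biased_method_readings",
    "simulate_study",
    "hypertension_prevalence",
]

#: E[max - min] / marginal SD for 25 samples of a stationary AR(1) process
#: with lag-1 correlation 0.7 (measured once by direct simulation, 4e5
#: replicates).  Used to convert the target 4-minute pressure swing into a
#: marginal SD: 25 samples at 10-s steps span 4 minutes.
AR1_RANGE_FACTOR_25 = 3.390

#: Minimum admissible pulse pressure (mmHg) enforced on generated values.
MIN_PULSE_PRESSURE = 5.0


def _as_rng(seed) -> np.random.Generator:
    """Accept an int seed, a SeedSequence, or an existing Generator."""
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=256)
def _matched_truncnorm_params(
    mean: float, sd: float, lower: float, upper: float
) -> tuple[float, float]:
    """Latent (mu, sigma) such that N(mu, sigma) truncated to [lower, upper]
    has the requested mean and SD.

    Naive truncation of N(mean, sd) shifts the moments whenever the range is
    asymmetric about the mean, so the configured table values would not be
    recovered in large samples; matching the post-truncation moments keeps
    the generator faithful to the published summary statistics.
    """

    def resid(p):
        mu, log_s = p
        s = float(np.exp(log_s))
        a, b = (lower - mu) / s, (upper - mu) / s
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=s, moments="mv")
        return [float(m) - mean, float(np.sqrt(v)) - sd]

    sol = optimize.root(resid, [mean, np.log(sd)], method="hybr")
    if not sol.success:  # pragma: no cover - defensive
        return mean, sd
    return float(sol.x[0]), float(np.exp(sol.x[1]))


@dataclass(frozen=True)
class TruncatedNormalSpec:
    """A marginal distribution: mean/SD on an admissible range.

    ``sd == 0`` degenerates to the constant ``mean``.  With finite bounds the
    draws are truncated-normal with the latent parameters chosen so that the
    *post-truncation* mean and SD equal the configured values.
    """

    mean: float
    sd: float
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        lo = -np.inf if self.lower is None else self.lower
        hi = np.inf if self.upper is None else self.upper
        if not lo < hi:
            raise ValueError("lower bound must be below upper bound")
        if not lo <= self.mean <= hi:
            raise ValueError("mean must lie within the admissible range")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, float(self.mean))
        if self.lower is None and self.upper is None:
            return rng.normal(self.mean, self.sd, size=n)
        lo = -np.inf if self.lower is None else self.lower
        hi = np.inf if self.upper is None else self.upper
        mu, s = _matched_truncnorm_params(self.mean, self.sd, lo, hi)
        a, b = (lo - mu) / s, (hi - mu) / s
        return stats.truncnorm.rvs(a, b, loc=mu, scale=s, size=n, random_state=rng)


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings for one simulated cohort.

    Defaults reproduce the published participant characteristics of the
    catheterization cohort (N=20): central aortic systolic 133.4 (SD 22.0) on
    96.7-179.3 mmHg, aortic diastolic 67.4 (SD 8.7) on 50.6-85.1 mmHg,
    radial-minus-aortic systolic augmentation averaging 12.3 mmHg, diastolic
    augmentation -1.2 mmHg (near zero), age 62 (SD 9), BMI 30.6 (SD 5.7),
    wrist circumference within the device's 13.5-23 cm admissible range,
    15/5 male/female and 75% already hypertensive.
    """

    aortic_systolic: TruncatedNormalSpec = TruncatedNormalSpec(133.4, 22.0, 96.7, 179.3)
    aortic_diastolic: TruncatedNormalSpec = TruncatedNormalSpec(67.4, 8.7, 50.6, 85.1)
    systolic_augmentation: TruncatedNormalSpec = TruncatedNormalSpec(12.3, 10.0, -10.0, 40.0)
    diastolic_augmentation: TruncatedNormalSpec = TruncatedNormalSpec(-1.2, 4.0, -15.0, 15.0)
    age: TruncatedNormalSpec = TruncatedNormalSpec(62.0, 9.0, 43.0, 77.0)
    bmi: TruncatedNormalSpec = TruncatedNormalSpec(30.6, 5.7, 21.0, 45.4)
    wrist_circumference: TruncatedNormalSpec = TruncatedNormalSpec(18.5, 1.5, 15.5, 21.5)
    male_fraction: float = 0.75
    hypertension_prevalence: float = 0.75
    #: Marginal beat-to-beat SDs; defaults give an expected 4-min swing of
    #: 20 mmHg systolic / 10 mmHg diastolic at 10-s sampling.
    variability_scale_systolic: float = 20.0 / AR1_RANGE_FACTOR_25
    variability_scale_diastolic: float = 10.0 / AR1_RANGE_FACTOR_25

    def __post_init__(self) -> None:
        if not self.aortic_systolic.mean > self.aortic_diastolic.mean:
            raise ValueError("mean systolic must exceed mean diastolic")
        for frac in (self.male_fraction, self.hypertension_prevalence):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.variability_scale_systolic < 0 or self.variability_scale_diastolic < 0:
            raise ValueError("variability scales must be >= 0")


@dataclass(frozen=True)
class PatientProfile:
    """One simulated participant's demographics and true hemodynamics."""

    patient_id: str
    age: float
    sex: str  # "male" | "female"
    bmi: float
    wrist_circumference: float
    hypertensive: bool
    mean_aortic_systolic: float
    mean_aortic_diastolic: float
    systolic_augmentation: float
    diastolic_augmentation: float
    variability_scale_systolic: float
    variability_scale_diastolic: float

    def __post_init__(self) -> None:
        if not self.mean_aortic_systolic > self.mean_aortic_diastolic:
            raise ValueError("mean aortic systolic must exceed diastolic")
        if self.variability_scale_systolic < 0 or self.variability_scale_diastolic < 0:
            raise ValueError("variability scales must be >= 0")
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")

    def site_means(self, site: Site) -> tuple[float, float]:
        """(systolic, diastolic) means at an arterial site."""
        if site is Site.AORTA:
            return self.mean_aortic_systolic, self.mean_aortic_diastolic
        if site is Site.RADIAL:
            return (
                self.mean_aortic_systolic + self.systolic_augmentation,
                self.mean_aortic_diastolic + self.diastolic_augmentation,
            )
        raise ValueError(f"unknown site {site!r}")


def simulate_cohort(
    n: int,
    config: CohortConfig | None = None,
    seed=0,
    id_prefix: str = "P",
) -> list[PatientProfile]:
    """Draw ``n`` patient profiles from the configured marginals.

    The hypertensive flag is assigned to exactly ``round(prevalence * n)``
    patients — those with the highest mean aortic systolic pressure — so the
    cohort prevalence is the configured value by construction (as in the
    study cohort, where 15/20 participants were already diagnosed).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or CohortConfig()
    rng = _as_rng(seed)

    age = config.age.sample(rng, n)
    sex = np.where(rng.random(n) < config.male_fraction, "male", "female")
    bmi = config.bmi.sample(rng, n)
    wrist = config.wrist_circumference.sample(rng, n)
    sys_ao = config.aortic_systolic.sample(rng, n)
    dia_ao = config.aortic_diastolic.sample(rng, n)
    aug_sys = config.systolic_augmentation.sample(rng, n)
    aug_dia = config.diastolic_augmentation.sample(rng, n)

    dia_ao = np.minimum(dia_ao, sys_ao - MIN_PULSE_PRESSURE)

    n_hyper = int(round(config.hypertension_prevalence * n))
    order = np.argsort(-sys_ao, kind="stable")
    hypertensive = np.zeros(n, dtype=bool)
    hypertensive[order[:n_hyper]] = True

    width = max(3, len(str(n)))
    return [
        PatientProfile(
            patient_id=f"{id_prefix}{i + 1:0{width}d}",
            age=float(age[i]),
            sex=str(sex[i]),
            bmi=float(bmi[i]),
            wrist_circumference=float(wrist[i]),
            hypertensive=bool(hypertensive[i]),
            mean_aortic_systolic=float(sys_ao[i]),
            mean_aortic_diastolic=float(dia_ao[i]),
            systolic_augmentation=float(aug_sys[i]),
            diastolic_augmentation=float(aug_dia[i]),
            variability_scale_systolic=config.variability_scale_systolic,
            variability_scale_diastolic=config.variability_scale_diastolic,
        )
        for i in range(n)
    ]


def hypertension_prevalence(cohort: Sequence[PatientProfile]) -> float:
    """Fraction of the cohort carrying a hypertension diagnosis."""
    if not cohort:
        raise ValueError("empty cohort")
    return sum(p.hypertensive for p in cohort) / len(cohort)


# ---------------------------------------------------------------------------
# Beat-level pressure series
# ---------------------------------------------------------------------------

@dataclass
class BeatSeries:
    """Systolic/diastolic pressures on a uniform time grid at one site."""

    site: Site
    times: np.ndarray
    systolic: np.ndarray
    diastolic: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.systolic = np.asarray(self.systolic, dtype=float)
        self.diastolic = np.asarray(self.diastolic, dtype=float)
        if not (len(self.times) == len(self.systolic) == len(self.diastolic)):
            raise ValueError("times/systolic/diastolic must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(self.systolic > self.diastolic):
            raise ValueError("systolic must exceed diastolic at every sample")

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def mean_systolic(self) -> float:
        return float(np.mean(self.systolic))

    @property
    def mean_diastolic(self) -> float:
        return float(np.mean(self.diastolic))

    @property
    def sd_systolic(self) -> float:
        return float(np.std(self.systolic, ddof=1)) if self.n > 1 else 0.0

    @property
    def sd_diastolic(self) -> float:
        return float(np.std(self.diastolic, ddof=1)) if self.n > 1 else 0.0

    def window(self, start: float, stop: float) -> "BeatSeries":
        """Sub-series with ``start <= t <= stop`` (inclusive)."""
        mask = (self.times >= start) & (self.times <= stop)
        if not mask.any():
            raise ValueError("window contains no samples")
        return BeatSeries(
            self.site, self.times[mask], self.systolic[mask], self.diastolic[mask]
        )


def _ar1_latent(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """Stationary AR(1) with marginal variance 1 and lag-1 correlation phi."""
    z = np.empty(n)
    z[0] = rng.standard_normal()
    if n > 1:
        innov = rng.standard_normal(n - 1) * np.sqrt(max(0.0, 1.0 - phi * phi))
        for k in range(1, n):
            z[k] = phi * z[k - 1] + innov[k - 1]
    return z


def _series_from_latent(profile: PatientProfile, site: Site, times: np.ndarray,
                        z: np.ndarray) -> BeatSeries:
    mu_s, mu_d = profile.site_means(site)
    sys_p = mu_s + profile.variability_scale_systolic * z
    dia_p = mu_d + profile.variability_scale_diastolic * z
    dia_p = np.minimum(dia_p, sys_p - MIN_PULSE_PRESSURE)
    return BeatSeries(site, times, sys_p, dia_p)


def simulate_beat_series(
    profile: PatientProfile,
    site: Site,
    duration: float = 240.0,
    step: float = 10.0,
    seed=0,
    lag1_corr: float = 0.7,
    corr_ref_lag: float = 10.0,
) -> BeatSeries:
    """Fluctuating pressures at ``site`` over ``duration`` seconds.

    A single latent stationary AR(1) process (lag-1 correlation ``lag1_corr``
    at a ``corr_ref_lag``-second lag, rescaled for other step sizes) drives
    both channels, scaled by the profile's per-channel variability scales.
    With the default scales the expected max-minus-min over 4 minutes at
    10-second sampling is ~20 mmHg systolic and ~10 mmHg diastolic.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if step > duration:
        raise ValueError("step must not exceed duration")
    if not isinstance(site, Site):
        site = Site(site)
    if not 0.0 <= lag1_corr < 1.0:
        raise ValueError("lag1_corr must lie in [0, 1)")
    rng = _as_rng(seed)
    n = int(round(duration / step)) + 1
    times = np.arange(n) * step
    phi = lag1_corr ** (step / corr_ref_lag) if lag1_corr > 0 else 0.0
    z = _ar1_latent(rng, n, phi)
    return _series_from_latent(profile, site, times, z)


# ---------------------------------------------------------------------------
# Stand-in oscillometric front end
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CuffDeflation:
    """Cuff deflation settings for the envelope stand-in.

    ``floor``/``ceiling`` default to ``min diastolic - margin`` and
    ``max systolic + margin``.
    """

    floor: float | None = None
    ceiling: float | None = None
    step: float = 1.0
    margin: float = 30.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("deflation step must be > 0")


@dataclass
class OscillometricEnvelope:
    """Oscillation amplitude (arbitrary units) versus cuff pressure (mmHg)."""

    pressures: np.ndarray  # ascending grid
    amplitude: np.ndarray
    support: tuple[float, float]

    def amplitude_at(self, p: float) -> float:
        lo, hi = self.support
        if p < lo or p > hi:
            return 0.0
        return float(np.interp(p, self.pressures, self.amplitude))

    @property
    def peak_pressure(self) -> float:
        return float(self.pressures[int(np.argmax(self.amplitude))])


@dataclass(frozen=True)
class OscillometricEstimate:
    systolic: float
    diastolic: float
    map_pressure: float


def oscillometric_envelope(
    window: BeatSeries, deflation: CuffDeflation | None = None
) -> OscillometricEnvelope:
    """Gaussian-kernel amplitude envelope for a beat window.

    Each beat contributes a Gaussian bump centered at its mean arterial
    pressure (MAP = diastolic + pulse pressure / 3) with width half the pulse
    pressure; the envelope is the average bump, zeroed outside
    ``[min diastolic - width, max systolic + width]``.  This is a documented
    stand-in for the device's proprietary waveform-to-pressure pipeline: it
    reproduces the one property the back end relies on (a unimodal envelope
    peaking at the window's MAP), nothing more.
    """
    if window.n == 0:
        raise ValueError("empty beat window")
    deflation = deflation or CuffDeflation()
    maps = window.diastolic + (window.systolic - window.diastolic) / 3.0
    widths = (window.systolic - window.diastolic) / 2.0
    w = float(np.mean(widths))
    support = (float(window.diastolic.min()) - w, float(window.systolic.max()) + w)

    floor = deflation.floor
    ceiling = deflation.ceiling
    if floor is None:
        floor = float(window.diastolic.min()) - deflation.margin
    if ceiling is None:
        ceiling = float(window.systolic.max()) + deflation.margin
    if floor > support[0] or ceiling < support[1]:
        raise ValueError("deflation range does not span the window's pressures")

    grid = np.arange(floor, ceiling + deflation.step / 2.0, deflation.step)
    # Anchor the exact mean MAP on the grid so the peak sits at the window MAP
    # rather than the nearest grid point.
    grid = np.union1d(grid, [float(np.mean(maps))])
    amp = np.mean(
        np.exp(-0.5 * ((grid[:, None] - maps[None, :]) / widths[None, :]) ** 2),
        axis=1,
    )
    amp[(grid < support[0]) | (grid > support[1])] = 0.0
    return OscillometricEnvelope(grid, amp, support)


def fixed_ratio_estimate(
    envelope: OscillometricEnvelope,
    ratios: tuple[float, float] = (0.55, 0.85),
) -> OscillometricEstimate:
    """Fixed-ratio read-out of an oscillometric envelope.

    MAP is the envelope argmax; systolic is the pressure above the peak where
    the amplitude first falls to ``systolic_ratio * max`` (linear
    interpolation between grid points), diastolic the analogous pressure
    below the peak at ``diastolic_ratio * max``.  Default ratios (0.55, 0.85)
    are the standard oscillometric literature values.
    """
    r_sys, r_dia = ratios
    for r in (r_sys, r_dia):
        if not 0.0 < r <= 1.0:
            raise ValueError("ratios must lie in (0, 1]")
    amp = envelope.amplitude
    p = envelope.pressures
    peak = int(np.argmax(amp))
    if peak == 0 or peak == len(amp) - 1:
        raise ValueError("envelope has no interior peak (monotone)")
    a_max = amp[peak]
    if a_max <= 0:
        raise ValueError("degenerate envelope (zero amplitude)")

    def crossing(direction: int, ratio: float) -> float:
        target = ratio * a_max
        j = peak
        while True:
            j += direction
            if j < 0 or j >= len(amp):
                raise ValueError("ratio crossing outside the deflation grid")
            if amp[j] <= target:
                prev = j - direction
                if amp[prev] == amp[j]:
                    return float(p[j])
                frac = (amp[prev] - target) / (amp[prev] - amp[j])
                return float(p[prev] + frac * (p[j] - p[prev]))

    map_pressure = float(p[peak])
    systolic = crossing(+1, r_sys) if r_sys < 1.0 else map_pressure
    diastolic = crossing(-1, r_dia) if r_dia < 1.0 else map_pressure
    return OscillometricEstimate(systolic, diastolic, map_pressure)


# ---------------------------------------------------------------------------
# Device and observer readings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeviceModel:
    """Affine miscalibration + noise of an automated cuff device.

    ``reading = intercept + slope * (sensed pressure) + N(0, noise_sd)`` per
    channel, where the sensed pressure is one draw from the beat window's
    distribution (the cuff acquires over a sub-interval of the fluctuating
    window, not its exact mean).  The reported per-reading SD combines the
    propagated beat-window SD with the device noise:
    ``sd = sqrt(slope^2 * window_sd^2 + noise_sd^2)``.
    """

    intercept_systolic: float = 0.0
    slope_systolic: float = 1.0
    intercept_diastolic: float = 0.0
    slope_diastolic: float = 1.0
    noise_sd_systolic: float = 0.0
    noise_sd_diastolic: float = 0.0

    def __post_init__(self) -> None:
        if self.slope_systolic <= 0 or self.slope_diastolic <= 0:
            raise ValueError("slopes must be > 0")
        if self.noise_sd_systolic < 0 or self.noise_sd_diastolic < 0:
            raise ValueError("noise SDs must be >= 0")


#: Identity pass-through (useful for noise-free limits in tests).
IDENTITY_DEVICE_MODEL = DeviceModel()

#: Default miscalibration for end-to-end fixtures: chosen so precalibration
#: absolute mean differences land near the 10.8 (systolic) / 16.1 (diastolic)
#: mmHg regime of a device still on its factory auscultatory calibration.
#: Purely illustrative; every field is configurable.
DEFAULT_DEVICE_MODEL = DeviceModel(
    intercept_systolic=-5.0,
    slope_systolic=0.95,
    intercept_diastolic=14.0,
    slope_diastolic=1.0,
    noise_sd_systolic=6.0,
    noise_sd_diastolic=4.0,
)

#: Stand-in upper-arm oscillometric comparator: under-reads central systolic
#: pressure by 12 mmHg (no brachial augmentation of the aortic waveform is
#: recovered by an arm cuff), used for the treatment-gap analysis.
DEFAULT_UPPER_ARM_MODEL = DeviceModel(
    intercept_systolic=-12.0,
    slope_systolic=1.0,
    intercept_diastolic=-1.2,
    slope_diastolic=1.0,
    noise_sd_systolic=5.0,
    noise_sd_diastolic=4.0,
)


def _guard_pulse(systolic: float, diastolic: float) -> tuple[float, float]:
    if systolic <= diastolic:
        diastolic = systolic - 1.0
    return systolic, diastolic


def device_reading(
    window: BeatSeries,
    model: DeviceModel,
    seed=0,
    *,
    patient_id: str = "",
    arm: Arm = Arm.LEFT,
    stage: Stage = Stage.INDEPENDENT,
    order_index: int = 0,
) -> BPReading:
    """One wrist-cuff reading from a beat window under a device model."""
    if window.n == 0:
        raise ValueError("empty beat window")
    rng = _as_rng(seed)
    base_s = rng.normal(window.mean_systolic, window.sd_systolic)
    base_d = rng.normal(window.mean_diastolic, window.sd_diastolic)
    sys_p = (
        model.intercept_systolic
        + model.slope_systolic * base_s
        + rng.normal(0.0, model.noise_sd_systolic)
    )
    dia_p = (
        model.intercept_diastolic
        + model.slope_diastolic * base_d
        + rng.normal(0.0, model.noise_sd_diastolic)
    )
    sd_s = float(np.hypot(model.slope_systolic * window.sd_systolic,
                          model.noise_sd_systolic))
    sd_d = float(np.hypot(model.slope_diastolic * window.sd_diastolic,
                          model.noise_sd_diastolic))
    sys_p, dia_p = _guard_pulse(float(sys_p), float(dia_p))
    return BPReading(
        patient_id=patient_id,
        method=Method.WRIST_CUFF,
        arm=arm,
        stage=stage,
        order_index=order_index,
        systolic=sys_p,
        diastolic=dia_p,
        sd_systolic=sd_s,
        sd_diastolic=sd_d,
    )


@dataclass(frozen=True)
class ObserverModel:
    """Auscultatory observer: Gaussian reading error, 2-mmHg terminal digits."""

    noise_sd_systolic: float = 4.0
    noise_sd_diastolic: float = 3.0
    rounding_base: float = 2.0
    n_observers: int = 2

    def __post_init__(self) -> None:
        if self.noise_sd_systolic < 0 or self.noise_sd_diastolic < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.n_observers < 1:
            raise ValueError("need at least one observer")


def auscultatory_reading(
    window: BeatSeries,
    observer: ObserverModel | None = None,
    seed=0,
    *,
    patient_id: str = "",
    arm: Arm = Arm.LEFT,
    stage: Stage = Stage.INDEPENDENT,
    order_index: int = 0,
) -> BPReading:
    """Manual auscultatory reading: window mean + observer noise, rounded to
    the nearest 2 mmHg (half away from zero).  With ``n_observers > 1`` the
    reported value is the average of the independent observers' readings."""
    if window.n == 0:
        raise ValueError("empty beat window")
    observer = observer or ObserverModel()
    rng = _as_rng(seed)
    sys_obs, dia_obs = [], []
    for _ in range(observer.n_observers):
        s = window.mean_systolic + rng.normal(0.0, observer.noise_sd_systolic)
        d = window.mean_diastolic + rng.normal(0.0, observer.noise_sd_diastolic)
        sys_obs.append(round_half_away(s, observer.rounding_base))
        dia_obs.append(round_half_away(d, observer.rounding_base))
    sys_p, dia_p = _guard_pulse(float(np.mean(sys_obs)), float(np.mean(dia_obs)))
    return BPReading(
        patient_id=patient_id,
        method=Method.UPPER_ARM_AUSCULTATORY,
        arm=arm,
        stage=stage,
        order_index=order_index,
        systolic=sys_p,
        diastolic=dia_p,
    )


def biased_method_readings(
    readings: Sequence[BPReading],
    model: DeviceModel,
    seed=0,
    method: Method = Method.UPPER_ARM_OSCILLOMETRIC,
    arm: Arm = Arm.LEFT,
) -> list[BPReading]:
    """Derive a comparator method's readings from reference readings.

    Each output reading is an affine transform of the reference values plus
    device noise — e.g. a synthetic upper-arm cuff that under-reads aortic
    systolic pressure.  Pairing metadata (patient, stage, order) is kept so
    the derived readings stay aligned with their references.
    """
    rng = _as_rng(seed)
    out = []
    for r in readings:
        sys_p = (
            model.intercept_systolic
            + model.slope_systolic * r.systolic
            + rng.normal(0.0, model.noise_sd_systolic)
        )
        dia_p = (
            model.intercept_diastolic
            + model.slope_diastolic * r.diastolic
            + rng.normal(0.0, model.noise_sd_diastolic)
        )
        sys_p, dia_p = _guard_pulse(float(sys_p), float(dia_p))
        out.append(
            BPReading(
                patient_id=r.patient_id,
                method=method,
                arm=arm,
                stage=r.stage,
                order_index=r.order_index,
                systolic=sys_p,
                diastolic=dia_p,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Full study schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtocolConfig:
    """Two-day measurement schedule settings.

    Day 1: a bilateral auscultatory equality screen (two observers per arm)
    plus four upper-arm baseline readings.  Day 2: ten readings per patient —
    two conditioning wrist readings (discarded downstream), two wrist readings
    each simultaneous with an intra-radial reading, and two wrist readings
    each simultaneous with an intra-aortic reading.  Simultaneity is
    implemented as an identical underlying beat window per pair.  An
    independent double-observer auscultatory comparison set (default 375
    measurements across 97 participants) is generated alongside.
    """

    n_day1_baseline: int = 4
    n_conditioning: int = 2
    n_pairs_per_site: int = 2
    window_duration: float = 60.0
    beat_step: float = 10.0
    inter_window_gap: float = 60.0
    lag1_corr: float = 0.7
    observer: ObserverModel = field(default_factory=ObserverModel)
    baseline_noise_sd: float = 3.0
    independent_measurements: int = 375
    independent_participants: int = 97
    independent_cohort: CohortConfig | None = None

    def __post_init__(self) -> None:
        if self.n_pairs_per_site < 1:
            raise ValueError("need at least one simultaneous pair per site")
        if self.independent_measurements > 0 and self.independent_participants < 1:
            raise ValueError("independent set needs at least one participant")
        if self.independent_measurements > 0 and (
            self.independent_measurements < self.independent_participants
        ):
            raise ValueError("independent set needs >= 1 measurement per participant")


@dataclass
class StudyDataset:
    """All readings generated by :func:`simulate_study`."""

    cohort: list[PatientProfile]
    readings: list[BPReading]
    independent_cohort: list[PatientProfile]
    independent_readings: list[BPReading]

    @property
    def all_readings(self) -> list[BPReading]:
        return self.readings + self.independent_readings

    def readings_for(self, patient_id: str) -> list[BPReading]:
        return [r for r in self.readings if r.patient_id == patient_id]

    def day2_session(self, patient_id: str) -> list[BPReading]:
        day2 = (Stage.CONDITIONING, Stage.RADIAL_SIMULTANEOUS, Stage.AORTIC_SIMULTANEOUS)
        return [r for r in self.readings_for(patient_id) if r.stage in day2]

    def day1_screen_readings(self, patient_id: str) -> dict[Arm, list[BPReading]]:
        out: dict[Arm, list[BPReading]] = {Arm.LEFT: [], Arm.RIGHT: []}
        for r in self.readings_for(patient_id):
            if r.stage is Stage.DAY1_BASELINE and r.method is Method.UPPER_ARM_AUSCULTATORY:
                out[r.arm].append(r)
        return out


def _session_series(
    profile: PatientProfile,
    rng: np.random.Generator,
    n_windows: int,
    protocol: ProtocolConfig,
) -> tuple[BeatSeries, BeatSeries, list[tuple[float, float]]]:
    """Shared-latent radial and aortic series spanning ``n_windows`` windows.

    Both sites are driven by the same AR(1) latent path, so windows cut from
    the two series at the same times are truly simultaneous.
    """
    slot = protocol.window_duration + protocol.inter_window_gap
    duration = (n_windows - 1) * slot + protocol.window_duration
    n = int(round(duration / protocol.beat_step)) + 1
    times = np.arange(n) * protocol.beat_step
    phi = protocol.lag1_corr ** (protocol.beat_step / 10.0) if protocol.lag1_corr > 0 else 0.0
    z = _ar1_latent(rng, n, phi)
    radial = _series_from_latent(profile, Site.RADIAL, times, z)
    aortic = _series_from_latent(profile, Site.AORTA, times, z)
    bounds = [(k * slot, k * slot + protocol.window_duration) for k in range(n_windows)]
    return radial, aortic, bounds


def simulate_study(
    cohort: Sequence[PatientProfile],
    protocol: ProtocolConfig | None = None,
    device: DeviceModel | None = None,
    seed=0,
) -> StudyDataset:
    """Generate the full two-day dataset for a cohort plus the independent set.

    Per patient: Day-1 bilateral auscultatory screen readings (2 observers x
    2 arms) and 4 upper-arm baseline readings; Day-2 the 10-reading schedule.
    Wrist-cuff readings sense the radial site (the cuff sits on the wrist);
    intra-arterial references are the exact window means at their site, so a
    wrist/aortic pair differs systematically by the patient's augmentation.
    """
    if not cohort:
        raise ValueError("empty cohort")
    protocol = protocol or ProtocolConfig()
    device = device or DEFAULT_DEVICE_MODEL

    root = np.random.SeedSequence(seed if not isinstance(seed, np.random.SeedSequence) else None)
    if isinstance(seed, np.random.SeedSequence):
        root = seed
    children = root.spawn(len(cohort) + 1)

    readings: list[BPReading] = []
    for profile, child in zip(cohort, children[:-1]):
        rng = np.random.default_rng(child)

        # --- Day 1: bilateral screen + baseline --------------------------
        n_day1_windows = 1 + protocol.n_day1_baseline
        day1_radial, _, bounds1 = _session_series(profile, rng, n_day1_windows, protocol)
        screen_window = day1_radial.window(*bounds1[0])
        for arm in (Arm.LEFT, Arm.RIGHT):
            for obs in range(2):
                single = replace(protocol.observer, n_observers=1)
                readings.append(
                    auscultatory_reading(
                        screen_window, single, rng,
                        patient_id=profile.patient_id, arm=arm,
                        stage=Stage.DAY1_BASELINE, order_index=obs,
                    )
                )
        for k in range(protocol.n_day1_baseline):
            w = day1_radial.window(*bounds1[1 + k])
            sys_p = w.mean_systolic + rng.normal(0.0, protocol.baseline_noise_sd)
            dia_p = w.mean_diastolic + rng.normal(0.0, protocol.baseline_noise_sd)
            sys_p, dia_p = _guard_pulse(sys_p, dia_p)
            readings.append(
                BPReading(
                    patient_id=profile.patient_id,
                    method=Method.UPPER_ARM_OSCILLOMETRIC,
                    arm=Arm.LEFT,
                    stage=Stage.DAY1_BASELINE,
                    order_index=k,
                    systolic=sys_p,
                    diastolic=dia_p,
                )
            )

        # --- Day 2: 10-reading schedule ----------------------------------
        n_windows = protocol.n_conditioning + 2 * protocol.n_pairs_per_site
        radial, aortic, bounds = _session_series(profile, rng, n_windows, protocol)
        w_idx = 0
        for k in range(protocol.n_conditioning):
            w = radial.window(*bounds[w_idx]); w_idx += 1
            readings.append(
                device_reading(w, device, rng, patient_id=profile.patient_id,
                               arm=Arm.LEFT, stage=Stage.CONDITIONING, order_index=k)
            )
        for stage, ref_site, ref_method, ref_arm in (
            (Stage.RADIAL_SIMULTANEOUS, Site.RADIAL, Method.INTRA_RADIAL, Arm.RIGHT),
            (Stage.AORTIC_SIMULTANEOUS, Site.AORTA, Method.INTRA_AORTIC, Arm.NONE),
        ):
            for k in range(protocol.n_pairs_per_site):
                lo, hi = bounds[w_idx]; w_idx += 1
                wrist_win = radial.window(lo, hi)
                ref_win = (radial if ref_site is Site.RADIAL else aortic).window(lo, hi)
                readings.append(
                    device_reading(wrist_win, device, rng,
                                   patient_id=profile.patient_id, arm=Arm.LEFT,
                                   stage=stage, order_index=k)
                )
                sys_p, dia_p = _guard_pulse(ref_win.mean_systolic, ref_win.mean_diastolic)
                readings.append(
                    BPReading(
                        patient_id=profile.patient_id,
                        method=ref_method,
                        arm=ref_arm,
                        stage=stage,
                        order_index=k,
                        systolic=sys_p,
                        diastolic=dia_p,
                    )
                )

    # --- Independent double-observer auscultatory set ---------------------
    independent_cohort: list[PatientProfile] = []
    independent_readings: list[BPReading] = []
    if protocol.independent_measurements > 0:
        ind_seq = children[-1]
        cohort_seq, meas_seq = ind_seq.spawn(2)
        independent_cohort = simulate_cohort(
            protocol.independent_participants,
            protocol.independent_cohort or CohortConfig(),
            seed=cohort_seq,
            id_prefix="Q",
        )
        n_meas = protocol.independent_measurements
        n_part = protocol.independent_participants
        base, extra = divmod(n_meas, n_part)
        rng = np.random.default_rng(meas_seq)
        for i, profile in enumerate(independent_cohort):
            k_i = base + (1 if i < extra else 0)
            if k_i == 0:
                continue
            radial, _, bounds = _session_series(profile, rng, k_i, protocol)
            for j in range(k_i):
                w = radial.window(*bounds[j])
                independent_readings.append(
                    device_reading(w, device, rng, patient_id=profile.patient_id,
                                   arm=Arm.LEFT, stage=Stage.INDEPENDENT, order_index=j)
                )
                independent_readings.append(
                    auscultatory_reading(
                        w, protocol.observer, rng,
                        patient_id=profile.patient_id, arm=Arm.RIGHT,
                        stage=Stage.INDEPENDENT, order_index=j,
                    )
                )

    return StudyDataset(list(cohort), readings, independent_cohort, independent_readings)
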