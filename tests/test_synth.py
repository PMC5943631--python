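"""Synthetic cohort, beat-series, and reading generators."""
import dataclasses

import numpy as np
import pytest

from wristbp import (
    BeatSeries,
    CohortConfig,
    CuffDeflation,
    DeviceModel,
    IDENTITY_DEVICE_MODEL,
    ObserverModel,
    ProtocolConfig,
    TruncatedNormalSpec,
    auscultatory_reading,
    device_reading,
    fixed_ratio_estimate,
    hypertension_prevalence,
    oscillometric_envelope,
    simulate_beat_series,
    simulate_cohort,
    simulate_study,
)
from wristbp.core import Method, Site, Stage


def _degenerate_config(**overrides) -> CohortConfig:
    """All marginals collapsed to their means (zero SD)."""
    base = CohortConfig()
    changes = {}
    for f in dataclasses.fields(base):
        v = getattr(base, f.name)
        if isinstance(v, TruncatedNormalSpec):
            changes[f.name] = TruncatedNormalSpec(v.mean, 0.0, v.lower, v.upper)
    changes.update(overrides)
    return dataclasses.replace(base, **changes)


class TestSimulateCohort:
    def test_sample_mean_matches_configured_table(self):
        cohort = simulate_cohort(10000, seed=123)
        sys_mean = np.mean([p.mean_aortic_systolic for p in cohort])
        dia_mean = np.mean([p.mean_aortic_diastolic for p in cohort])
        assert abs(sys_mean - 133.4) < 1.0
        assert abs(dia_mean - 67.4) < 0.5
        sys_sd = np.std([p.mean_aortic_systolic for p in cohort], ddof=1)
        assert abs(sys_sd - 22.0) < 1.0

    def test_draws_respect_configured_ranges(self):
        cohort = simulate_cohort(5000, seed=9)
        sys_p = np.array([p.mean_aortic_systolic for p in cohort])
        assert sys_p.min() >= 96.7 and sys_p.max() <= 179.3
        wrist = np.array([p.wrist_circumference for p in cohort])
        assert wrist.min() >= 15.5 and wrist.max() <= 21.5

    def test_seeded_determinism(self):
        a = simulate_cohort(50, seed=5)
        b = simulate_cohort(50, seed=5)
        assert a == b
        assert simulate_cohort(50, seed=6) != a

    def test_zero_sd_collapses_to_means(self):
        cohort = simulate_cohort(10, _degenerate_config(), seed=0)
        for p in cohort:
            assert p.mean_aortic_systolic == 133.4
            assert p.mean_aortic_diastolic == 67.4
            assert p.systolic_augmentation == 12.3
            assert p.age == 62.0

    def test_prevalence_bookkeeping(self, cohort20):
        assert sum(p.hypertensive for p in cohort20) == 15
        assert hypertension_prevalence(cohort20) == 0.75

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_cohort(0)
        with pytest.raises(ValueError):
            CohortConfig(
                aortic_systolic=TruncatedNormalSpec(60.0, 5.0),
                aortic_diastolic=TruncatedNormalSpec(80.0, 5.0),
            )


class TestBeatSeries:
    def test_grid_arithmetic(self, profile):
        s = simulate_beat_series(profile, Site.AORTA, duration=240, step=10, seed=1)
        assert s.n == 25
        assert s.times[0] == 0.0 and s.times[-1] == 240.0
        assert np.allclose(np.diff(s.times), 10.0)

    def test_zero_variability_constant_at_site_means(self, profile):
        quiet = dataclasses.replace(
            profile, variability_scale_systolic=0.0, variability_scale_diastolic=0.0
        )
        for site in (Site.AORTA, Site.RADIAL):
            s = simulate_beat_series(quiet, site, seed=3)
            mu_s, mu_d = quiet.site_means(site)
            assert np.all(s.systolic == mu_s)
            assert np.all(s.diastolic == mu_d)

    def test_radial_site_adds_augmentation(self, profile):
        a = simulate_beat_series(profile, Site.AORTA, seed=4)
        r = simulate_beat_series(profile, Site.RADIAL, seed=4)
        assert np.allclose(r.systolic - a.systolic, profile.systolic_augmentation)

    def test_pulse_pressure_always_positive(self, profile):
        for seed in range(20):
            s = simulate_beat_series(profile, Site.AORTA, seed=seed)
            assert np.all(s.systolic > s.diastolic)

    def test_expected_four_minute_swing(self, profile):
        """Mean max-minus-min over 4 min at 10-s sampling is ~20/10 mmHg."""
        sys_ranges, dia_ranges = [], []
        for seed in range(1000):
            s = simulate_beat_series(profile, Site.AORTA, 240, 10, seed=seed)
            sys_ranges.append(np.ptp(s.systolic))
            dia_ranges.append(np.ptp(s.diastolic))
        assert abs(np.mean(sys_ranges) - 20.0) < 3.0
        assert abs(np.mean(dia_ranges) - 10.0) < 1.5

    def test_invalid_inputs(self, profile):
        with pytest.raises(ValueError):
            simulate_beat_series(profile, Site.AORTA, duration=5, step=10)
        with pytest.raises(ValueError):
            simulate_beat_series(profile, "femoral")


class TestOscillometricStandIn:
    def test_constant_beats_peak_at_map(self, constant_window):
        env = oscillometric_envelope(constant_window)
        map_true = 80.0 + (120.0 - 80.0) / 3.0
        assert env.peak_pressure == pytest.approx(map_true, abs=1e-9)

    def test_amplitude_zero_outside_support(self, constant_window):
        env = oscillometric_envelope(constant_window)
        lo, hi = env.support
        assert env.amplitude_at(lo - 1.0) == 0.0
        assert env.amplitude_at(hi + 1.0) == 0.0

    def test_gaussian_closed_form_for_constant_beats(self, constant_window):
        env = oscillometric_envelope(constant_window)
        map_true, width = 280.0 / 3.0, 20.0
        inside = (env.pressures >= env.support[0]) & (env.pressures <= env.support[1])
        expected = np.exp(-0.5 * ((env.pressures[inside] - map_true) / width) ** 2)
        assert np.allclose(env.amplitude[inside], expected, atol=1e-12)

    def test_deflation_not_spanning_raises(self, constant_window):
        with pytest.raises(ValueError):
            oscillometric_envelope(constant_window, CuffDeflation(floor=90.0))

    def test_triangle_crossings(self):
        from wristbp import OscillometricEnvelope

        p = np.arange(60.0, 140.5, 1.0)
        env = OscillometricEnvelope(p, 1 - np.abs(p - 100.0) / 40.0, (60.0, 140.0))
        est = fixed_ratio_estimate(env, (0.55, 0.85))
        assert est.systolic == pytest.approx(118.0, abs=1e-6)
        assert est.diastolic == pytest.approx(94.0, abs=1e-6)
        assert est.map_pressure == pytest.approx(100.0, abs=1e-9)

    def test_unit_ratios_collapse_to_peak(self, constant_window):
        env = oscillometric_envelope(constant_window)
        est = fixed_ratio_estimate(env, (1.0, 1.0))
        assert est.systolic == est.diastolic == est.map_pressure == env.peak_pressure

    def test_symmetric_envelope_symmetric_crossings(self, constant_window):
        # symmetry holds up to the linear-interpolation error of the grid
        env = oscillometric_envelope(constant_window, CuffDeflation(step=0.05))
        est = fixed_ratio_estimate(env, (0.7, 0.7))
        assert est.systolic - est.map_pressure == pytest.approx(
            est.map_pressure - est.diastolic, abs=1e-3
        )

    def test_monotone_envelope_raises(self):
        from wristbp import OscillometricEnvelope

        p = np.arange(60.0, 140.5, 1.0)
        env = OscillometricEnvelope(p, np.linspace(0.1, 1.0, len(p)), (60.0, 140.0))
        with pytest.raises(ValueError):
            fixed_ratio_estimate(env)


class TestDeviceReading:
    def test_identity_passthrough_constant_window(self, constant_window):
        r = device_reading(constant_window, IDENTITY_DEVICE_MODEL, seed=1)
        assert (r.systolic, r.diastolic) == (120.0, 80.0)
        assert (r.sd_systolic, r.sd_diastolic) == (0.0, 0.0)
        assert r.method is Method.WRIST_CUFF

    def test_affine_shift_exact_on_constant_window(self, constant_window):
        model = DeviceModel(intercept_systolic=10.0)
        r = device_reading(constant_window, model, seed=2)
        assert r.systolic == 130.0

    def test_reported_sd_matches_replicate_sd(self, profile):
        """Monte-Carlo check of sd = sqrt(slope^2 var_window + noise^2)."""
        window = simulate_beat_series(profile, Site.RADIAL, 60, 10, seed=77)
        model = DeviceModel(slope_systolic=0.95, noise_sd_systolic=6.0,
                            noise_sd_diastolic=4.0)
        readings = [device_reading(window, model, seed=s) for s in range(10000)]
        reported = readings[0].sd_systolic
        empirical = np.std([r.systolic for r in readings], ddof=1)
        assert abs(empirical - reported) / reported < 0.05

    def test_empty_window_raises(self):
        empty = BeatSeries(Site.RADIAL, [], [], [])
        with pytest.raises(ValueError):
            device_reading(empty, IDENTITY_DEVICE_MODEL)


class TestAuscultatoryReading:
    def test_rounding_to_even_scale(self):
        window = BeatSeries(Site.RADIAL, [0.0, 10.0], [121.0, 121.0], [79.0, 79.0])
        obs = ObserverModel(0.0, 0.0, 2.0, n_observers=1)
        r = auscultatory_reading(window, obs, seed=0)
        assert (r.systolic, r.diastolic) == (122.0, 80.0)

    def test_two_observers_degenerate_to_single(self, constant_window):
        one = auscultatory_reading(constant_window, ObserverModel(0, 0, 2, 1), seed=0)
        two = auscultatory_reading(constant_window, ObserverModel(0, 0, 2, 2), seed=0)
        assert (one.systolic, one.diastolic) == (two.systolic, two.diastolic)

    def test_replicate_sd_matches_observer_noise(self, constant_window):
        obs = ObserverModel(4.0, 3.0, 2.0, n_observers=1)
        vals = [
            auscultatory_reading(constant_window, obs, seed=s).systolic
            for s in range(5000)
        ]
        # rounding to 2 mmHg adds ~2^2/12 of variance on top of noise_sd^2
        assert abs(np.std(vals, ddof=1) - 4.0) / 4.0 < 0.10


class TestSimulateStudy:
    def test_ten_day2_readings_per_patient(self, cohort20):
        proto = ProtocolConfig(independent_measurements=0)
        ds = simulate_study(cohort20, proto, seed=1)
        for p in cohort20:
            session = ds.day2_session(p.patient_id)
            assert len(session) == 10
            wrist = [r for r in session if r.method is Method.WRIST_CUFF]
            assert len(wrist) == 6  # 2 conditioning + 2 radial + 2 aortic
            assert sum(r.method is Method.INTRA_RADIAL for r in session) == 2
            assert sum(r.method is Method.INTRA_AORTIC for r in session) == 2

    def test_day1_readings_per_patient(self, cohort20):
        proto = ProtocolConfig(independent_measurements=0)
        ds = simulate_study(cohort20[:3], proto, seed=1)
        pid = cohort20[0].patient_id
        screen = ds.day1_screen_readings(pid)
        assert {arm: len(rs) for arm, rs in screen.items()} == {a: 2 for a in screen}
        baseline = [
            r
            for r in ds.readings_for(pid)
            if r.stage is Stage.DAY1_BASELINE and r.method is Method.UPPER_ARM_OSCILLOMETRIC
        ]
        assert len(baseline) == 4

    def test_noise_free_wrist_equals_reference(self):
        cohort = simulate_cohort(4, _degenerate_config(), seed=0)
        quiet = [
            dataclasses.replace(p, variability_scale_systolic=0.0,
                                variability_scale_diastolic=0.0)
            for p in cohort
        ]
        proto = ProtocolConfig(
            observer=ObserverModel(0.0, 0.0, 2.0, 2),
            baseline_noise_sd=0.0,
            independent_measurements=0,
        )
        ds = simulate_study(quiet, proto, IDENTITY_DEVICE_MODEL, seed=0)
        for p in quiet:
            session = ds.day2_session(p.patient_id)
            for stage, ref_method in (
                (Stage.RADIAL_SIMULTANEOUS, Method.INTRA_RADIAL),
                (Stage.AORTIC_SIMULTANEOUS, Method.INTRA_AORTIC),
            ):
                wrist = {r.order_index: r for r in session
                         if r.stage is stage and r.method is Method.WRIST_CUFF}
                refs = {r.order_index: r for r in session
                        if r.stage is stage and r.method is ref_method}
                for k in wrist:
                    if ref_method is Method.INTRA_RADIAL:
                        assert wrist[k].systolic == pytest.approx(refs[k].systolic, abs=1e-9)
                        assert wrist[k].diastolic == pytest.approx(refs[k].diastolic, abs=1e-9)
                    else:
                        assert wrist[k].systolic - refs[k].systolic == pytest.approx(
                            p.systolic_augmentation, abs=1e-9
                        )

    def test_independent_set_shape(self, cohort20):
        proto = ProtocolConfig(independent_measurements=375, independent_participants=97)
        ds = simulate_study(cohort20[:2], proto, seed=2)
        assert len(ds.independent_cohort) == 97
        wrist = [r for r in ds.independent_readings if r.method is Method.WRIST_CUFF]
        ausc = [r for r in ds.independent_readings if r.method is Method.UPPER_ARM_AUSCULTATORY]
        assert len(wrist) == 375 and len(ausc) == 375
        per_patient = {}
        for r in wrist:
            per_patient[r.patient_id] = per_patient.get(r.patient_id, 0) + 1
        counts = set(per_patient.values())
        assert len(per_patient) == 97 and counts <= {3, 4}

    def test_seeded_determinism(self, cohort20):
        proto = ProtocolConfig(independent_measurements=20, independent_participants=5)
        a = simulate_study(cohort20[:3], proto, seed=9)
        b = simulate_study(cohort20[:3], proto, seed=9)
        assert a.readings == b.readings
        assert a.independent_readings == b.independent_readings

    def test_every_reading_has_positive_pulse_pressure(self, cohort20):
        ds = simulate_study(cohort20[:5], ProtocolConfig(independent_measurements=0), seed=3)
        assert all(r.systolic > r.diastolic for r in ds.readings)
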