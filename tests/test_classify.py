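"""Threshold classification, concordance, treatment gap, Fisher exact."""
import math

import numpy as np
import pytest
from scipy import stats as sps

from wristbp import (
    CHEP,
    SPRINT,
    ConcordanceTable,
    ThresholdSet,
    biased_method_readings,
    classify_reading,
    concordance,
    fisher_exact_one_tailed,
    method_comparison,
    treatment_gap,
)
from wristbp.core import Arm, BPReading, Method, Stage
from wristbp.synth import DeviceModel


def _reading(systolic, diastolic, pid="P1", order=0, method=Method.INTRA_AORTIC):
    return BPReading(pid, method, Arm.NONE, Stage.AORTIC_SIMULTANEOUS, order,
                     systolic, diastolic)


def enumerate_fisher(table: ConcordanceTable, alternative: str) -> float:
    """Full hypergeometric enumeration oracle using math.comb only."""
    r1, c1, n = table.a + table.b, table.a + table.c, table.total
    denom = math.comb(n, c1)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    p = 0.0
    for k in range(lo, hi + 1):
        if (alternative == "less" and k <= table.a) or (
            alternative == "greater" and k >= table.a
        ):
            p += math.comb(r1, k) * math.comb(n - r1, c1 - k) / denom
    return min(1.0, p)


class TestClassifyReading:
    @pytest.mark.parametrize(
        "systolic,diastolic,thresholds,expected",
        [
            (136.0, 80.0, CHEP, True),   # systolic rule
            (130.0, 86.0, CHEP, True),   # diastolic OR rule
            (135.0, 70.0, CHEP, True),   # inclusive bound
            (134.9, 84.9, CHEP, False),
            (119.0, 70.0, SPRINT, False),
            (120.0, 70.0, SPRINT, True),
            (110.0, 95.0, SPRINT, False),  # no diastolic criterion
        ],
    )
    def test_threshold_rules(self, systolic, diastolic, thresholds, expected):
        assert classify_reading(_reading(systolic, diastolic), thresholds) is expected

    def test_monotone_in_pressures(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            s, d = rng.uniform(90, 180), rng.uniform(50, 100)
            d = min(d, s - 5)
            base = classify_reading(_reading(s, d), CHEP)
            raised = classify_reading(_reading(s + 10, d + 5), CHEP)
            assert raised >= base

    def test_raising_threshold_never_adds_positives(self):
        rng = np.random.default_rng(1)
        readings = [
            _reading(s, min(dd, s - 5))
            for s, dd in zip(rng.uniform(90, 180, 100), rng.uniform(50, 100, 100))
        ]
        low = ThresholdSet("low", 120.0, 80.0)
        high = ThresholdSet("high", 140.0, 90.0)
        n_low = sum(classify_reading(r, low) for r in readings)
        n_high = sum(classify_reading(r, high) for r in readings)
        assert n_high <= n_low


class TestConcordance:
    def test_all_four_cells(self):
        table = concordance([True, False, True, False], [True, True, False, False])
        assert (table.a, table.b, table.c, table.d) == (1, 1, 1, 1)

    def test_identical_vectors(self):
        calls = [True, False, True]
        table = concordance(calls, calls)
        assert table.b == table.c == 0

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(2)
        m = rng.random(50) < 0.4
        r = rng.random(50) < 0.5
        table = concordance(m, r)
        expected = {"a": 0, "b": 0, "c": 0, "d": 0}
        for mi, ri in zip(m, r):
            key = "a" if ri and mi else "b" if ri else "c" if mi else "d"
            expected[key] += 1
        assert (table.a, table.b, table.c, table.d) == tuple(
            expected[k] for k in "abcd"
        )

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            concordance([True], [True, False])


class TestTreatmentGap:
    def test_arithmetic(self):
        assert treatment_gap(ConcordanceTable(8, 2, 0, 5)) == pytest.approx(0.20)

    def test_perfect_sensitivity(self):
        assert treatment_gap(ConcordanceTable(10, 0, 1, 5)) == 0.0

    def test_no_reference_positives_raises(self):
        with pytest.raises(ValueError):
            treatment_gap(ConcordanceTable(0, 0, 3, 5))

    def test_complements_sensitivity(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 20, 4)
            if a + b == 0:
                continue
            table = ConcordanceTable(int(a), int(b), int(c), int(d))
            assert treatment_gap(table) == pytest.approx(1.0 - table.sensitivity)


class TestFisherExact:
    def test_perfect_concordance_greater_tail(self):
        p = fisher_exact_one_tailed(ConcordanceTable(10, 0, 0, 10), "greater")
        assert p == pytest.approx(1.0 / math.comb(20, 10), rel=1e-9)

    def test_no_association_table(self):
        for alt in ("less", "greater"):
            assert fisher_exact_one_tailed(ConcordanceTable(5, 5, 5, 5), alt) > 0.5

    def test_degenerate_margins_give_one(self):
        assert fisher_exact_one_tailed(ConcordanceTable(0, 0, 4, 6)) == 1.0
        assert fisher_exact_one_tailed(ConcordanceTable(0, 4, 0, 6)) == 1.0

    def test_probability_bounds(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, 4))
            if a + b + c + d == 0:
                continue
            for alt in ("less", "greater"):
                p = fisher_exact_one_tailed(ConcordanceTable(a, b, c, d), alt)
                assert 0.0 < p <= 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, 4))
            if a + b + c + d == 0 or a + b + c + d > 60:
                continue
            table = ConcordanceTable(a, b, c, d)
            for alt in ("less", "greater"):
                assert fisher_exact_one_tailed(table, alt) == pytest.approx(
                    enumerate_fisher(table, alt), abs=1e-12
                )

    def test_matches_scipy_orientation(self):
        table = ConcordanceTable(3, 9, 8, 2)
        expected = sps.fisher_exact([[3, 9], [8, 2]], alternative="less")[1]
        assert fisher_exact_one_tailed(table, "less") == pytest.approx(expected, rel=1e-9)


class TestMethodComparison:
    def _aligned(self, deltas):
        refs = [
            _reading(s, d, pid=f"P{i}", order=0)
            for i, (s, d) in enumerate([(150, 70), (128, 88), (118, 66), (140, 80)])
        ]
        other = [
            r.replace(systolic=r.systolic + ds, diastolic=r.diastolic + dd,
                      method=Method.UPPER_ARM_OSCILLOMETRIC, arm=Arm.LEFT)
            for r, (ds, dd) in zip(refs, deltas)
        ]
        return refs, other

    def test_identical_method_is_perfect(self):
        refs, _ = self._aligned([(0, 0)] * 4)
        rows = method_comparison(
            {"ref": refs, "same": [r.replace(method=Method.WRIST_CUFF,
                                             sd_systolic=1.0, sd_diastolic=1.0)
                                   for r in refs]},
            "ref",
            [CHEP],
        )
        (row,) = rows
        assert row.sensitivity == 1.0
        assert row.treatment_gap == 0.0
        assert row.fisher_p == 1.0

    def test_biased_method_shows_gap(self, cohort20):
        from wristbp import ProtocolConfig, assemble_day2_pairs, simulate_study

        ds = simulate_study(cohort20, ProtocolConfig(independent_measurements=0), seed=21)
        refs = []
        for p in cohort20:
            _, aortic = assemble_day2_pairs(ds.day2_session(p.patient_id))
            refs += [q.reference for q in aortic]
        biased = biased_method_readings(
            refs, DeviceModel(intercept_systolic=-12.0, noise_sd_systolic=5.0,
                              noise_sd_diastolic=4.0), seed=3
        )
        (row,) = method_comparison({"ref": refs, "arm": biased}, "ref", [CHEP])
        assert row.treatment_gap > 0.0
        assert row.positives_method < row.positives_reference

    def test_patient_level_grouping(self):
        refs, other = self._aligned([(0, 0), (0, 0), (0, 0), (0, 0)])
        refs = refs + [r.replace(order_index=1) for r in refs]
        other = other + [r.replace(order_index=1) for r in other]
        rows = method_comparison({"ref": refs, "arm": other}, "ref", [CHEP], by="patient")
        assert rows[0].n == 4  # four patients, not eight measures

    def test_misaligned_readings_raise(self):
        refs, other = self._aligned([(0, 0)] * 4)
        with pytest.raises(ValueError, match="aligned"):
            method_comparison({"ref": refs, "arm": other[:-1] + [
                other[-1].replace(patient_id="P99")]}, "ref", [CHEP])

    def test_missing_reference_raises(self):
        refs, other = self._aligned([(0, 0)] * 4)
        with pytest.raises(ValueError):
            method_comparison({"arm": other}, "ref", [CHEP])
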