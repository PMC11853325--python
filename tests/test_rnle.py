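"""Revised NIOSH lifting equation: multipliers, RWL, LI and risk labels."""

import math

import pytest
from hypothesis import given, strategies as st

from liftrisk import rnle


def make_task(**overrides):
    base = dict(load_weight=10.0, horizontal_distance=20.0, vertical_origin=25.0,
                vertical_destination=65.0, frequency=5.0, duration_category="le1h",
                coupling="poor", unit_system="US")
    base.update(overrides)
    return rnle.LiftingTask(**base)


class TestLoadConstant:
    def test_standard_manual_values(self):
        assert rnle.load_constant("standard", unit_system="US") == 51.0
        assert rnle.load_constant("standard", unit_system="metric") == 23.0

    @pytest.mark.parametrize("sex,age,expected_kg", [
        ("M", 30, 25.0), ("M", 50, 20.0), ("F", 30, 20.0), ("F", 50, 15.0),
    ])
    def test_demographic_bands(self, sex, age, expected_kg):
        lc = rnle.load_constant("demographic", rnle.Demographics(sex, age), "metric")
        assert lc == expected_kg

    def test_demographic_requires_demographics(self):
        with pytest.raises(rnle.RnleError):
            rnle.load_constant("demographic", None, "US")


class TestMultipliers:
    @pytest.mark.parametrize("h,expected", [(20, 0.5), (8, 1.0), (30, 0.0)])
    def test_horizontal(self, h, expected):
        assert rnle.horizontal_multiplier(h) == pytest.approx(expected)

    @pytest.mark.parametrize("v,expected", [(30, 1.0), (65, 0.7375), (25, 0.9625)])
    def test_vertical(self, v, expected):
        assert rnle.vertical_multiplier(v) == pytest.approx(expected)

    @pytest.mark.parametrize("d,expected", [(40, 0.865), (5, 1.0), (70, 0.82 + 1.8 / 70)])
    def test_distance(self, d, expected):
        assert rnle.distance_multiplier(d) == pytest.approx(expected)

    @pytest.mark.parametrize("a,expected", [(0, 1.0), (90, 0.712), (135, 0.568)])
    def test_asymmetric(self, a, expected):
        assert rnle.asymmetric_multiplier(a) == pytest.approx(expected)

    @pytest.mark.parametrize("f,dur,v,expected", [
        (5, "le1h", 65, 0.80),
        (0.2, "le1h", 10, 1.00),
        (16, "le1h", 10, 0.00),
        (9, "le8h", 10, 0.00),   # long duration, low hands: out of range
        (9, "le8h", 40, 0.15),
    ])
    def test_frequency_table(self, f, dur, v, expected):
        assert rnle.frequency_multiplier(f, dur, v) == expected

    def test_frequency_rounds_up_between_rows(self):
        # 4.3 lifts/min uses the 5/min row (conservative direction)
        assert rnle.frequency_multiplier(4.3, "le1h", 40) == 0.80

    def test_frequency_rejects_bad_duration(self):
        with pytest.raises(rnle.RnleError):
            rnle.frequency_multiplier(5, "le4h", 40)

    @pytest.mark.parametrize("coupling,v,expected", [
        ("good", 10, 1.0), ("good", 65, 1.0),
        ("poor", 65, 0.90), ("fair", 20, 0.95), ("fair", 40, 1.00),
    ])
    def test_coupling(self, coupling, v, expected):
        assert rnle.coupling_multiplier(coupling, v) == expected

    def test_grab_multiplier_alias(self):
        assert rnle.grab_multiplier is rnle.coupling_multiplier

    def test_negative_inputs_rejected(self):
        with pytest.raises(rnle.RnleError):
            rnle.horizontal_multiplier(-1)
        with pytest.raises(rnle.RnleError):
            rnle.asymmetric_multiplier(-5)


class TestAssessTask:
    def test_printed_low_risk_task(self):
        a = rnle.assess_task(make_task())
        assert round(a.LI, 2) == 0.85
        assert a.risk_category == "acceptable"
        assert a.binary_label == 0

    def test_printed_high_risk_task(self):
        a = rnle.assess_task(make_task(load_weight=18.0))
        assert round(a.LI, 2) == 1.54
        assert a.risk_category == "increased"
        assert a.binary_label == 1

    def test_destination_governs_for_printed_task(self):
        a = rnle.assess_task(make_task())
        assert a.RWL_destination < a.RWL_origin
        assert a.LI == pytest.approx(10.0 / a.RWL_destination)

    def test_boundary_load_is_acceptable(self):
        a = rnle.assess_task(make_task())
        boundary = rnle.assess_task(make_task(load_weight=min(a.RWL_origin,
                                                              a.RWL_destination)))
        assert boundary.LI == pytest.approx(1.0)
        assert boundary.risk_category == "acceptable"
        assert boundary.binary_label == 0

    def test_zero_multiplier_gives_infinite_li_high_risk(self):
        a = rnle.assess_task(make_task(horizontal_distance=30.0))  # HM = 0
        assert a.RWL_origin == 0.0
        assert math.isinf(a.LI)
        assert a.risk_category == "high"
        assert a.binary_label == 1

    def test_travel_distance_defaults_to_vertical_span(self):
        task = make_task()
        assert task.travel_distance == 40.0

    def test_li_linear_in_load(self):
        li1 = rnle.assess_task(make_task(load_weight=7.0)).LI
        li2 = rnle.assess_task(make_task(load_weight=14.0)).LI
        assert li2 == pytest.approx(2.0 * li1)

    def test_metric_and_us_evaluations_agree(self):
        # The official metric-form constants (25/H, 0.003 slope, 4.5/D,
        # 23 kg) are rounded relative to the inch/pound forms, so the two
        # unit systems agree only to a few percent, not exactly.
        us = rnle.assess_task(make_task())
        metric = rnle.assess_task(make_task(
            load_weight=10 * 0.45359237, horizontal_distance=20 * 2.54,
            vertical_origin=25 * 2.54, vertical_destination=65 * 2.54,
            unit_system="metric"))
        assert metric.LI == pytest.approx(us.LI, rel=0.05)


@given(
    h=st.floats(0, 30), v=st.floats(0, 80), d=st.floats(0, 80),
    a=st.floats(0, 180), f=st.floats(0.1, 20),
    dur=st.sampled_from(rnle.DURATIONS), coupling=st.sampled_from(rnle.COUPLINGS),
)
def test_all_multipliers_within_unit_interval(h, v, d, a, f, dur, coupling):
    values = [rnle.horizontal_multiplier(h), rnle.vertical_multiplier(v),
              rnle.distance_multiplier(d), rnle.asymmetric_multiplier(a),
              rnle.frequency_multiplier(f, dur, v), rnle.coupling_multiplier(coupling, v)]
    assert all(0.0 <= m <= 1.0 for m in values)


@given(st.floats(10, 24), st.floats(1, 5))
def test_rwl_monotone_nonincreasing_in_horizontal_distance(h, dh):
    a1 = rnle.assess_task(make_task(horizontal_distance=h))
    a2 = rnle.assess_task(make_task(horizontal_distance=h + dh))
    assert a2.RWL_origin <= a1.RWL_origin + 1e-12


@given(st.floats(0, 120), st.floats(1, 15))
def test_rwl_monotone_nonincreasing_in_asymmetry(a, da):
    r1 = rnle.assess_task(make_task(asymmetry_angle=a))
    r2 = rnle.assess_task(make_task(asymmetry_angle=a + da))
    assert r2.RWL_origin <= r1.RWL_origin + 1e-12


@given(st.floats(0, 39), st.floats(1, 10))
def test_rwl_monotone_in_distance_from_vertical_optimum(dv, extra):
    # moving the origin farther from knuckle height never raises the RWL
    # (travel distance held fixed so only VM varies)
    r1 = rnle.assess_task(make_task(vertical_origin=30 + dv, travel_distance=40))
    r2 = rnle.assess_task(make_task(vertical_origin=min(30 + dv + extra, 70),
                                    travel_distance=40))
    assert r2.RWL_origin <= r1.RWL_origin + 1e-12


def test_batch_csv_roundtrip(tmp_path):
    tasks = tmp_path / "tasks.csv"
    tasks.write_text(
        "load_weight,horizontal_distance,vertical_origin,vertical_destination,"
        "travel_distance,asymmetry_angle,frequency,duration_category,coupling,unit_system\n"
        "10,20,25,65,,0,5,le1h,poor,US\n"
        "18,20,25,65,40,0,5,le1h,poor,US\n")
    out = tmp_path / "assessments.csv"
    assert rnle.assess_tasks_csv(tasks, out) == 2
    lines = out.read_text().strip().splitlines()
    assert len(lines) == 3
    assert ",0.85," in lines[1]
    assert ",1.54," in lines[2]
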