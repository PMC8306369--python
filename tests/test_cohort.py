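from datetime import date

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mihmm.cohort import (
    AdmissionRecord,
    Observation,
    PatientSeries,
    add_censored_rows,
    annualize,
    build_cohort,
    frame_to_series,
    gap_years,
    read_admissions_csv,
    series_to_frame,
)
from mihmm.simulate import tiny_cohort
from mihmm.states import HealthState

from conftest import make_series


def rec(pid, d, code, age=70, sex="female", indig="no", first=True, death=None):
    return AdmissionRecord(pid, d, code, age, sex, indig, first, death)


# ---------------------------------------------------------------------------
# annualize
# ---------------------------------------------------------------------------


def test_within_year_most_severe_state_wins():
    s = annualize(
        [
            rec("a", date(2010, 2, 1), "I20.0"),
            rec("a", date(2010, 7, 1), "I21.4"),
        ]
    )
    assert len(s.observations) == 1
    assert s.observations[0].state is HealthState.NSTEMI

    s = annualize(
        [
            rec("a", date(2010, 2, 1), "I21.2"),
            rec("a", date(2010, 7, 1), "I21.4"),
            rec("a", date(2010, 8, 1), "I20.0"),
        ]
    )
    assert s.observations[0].state is HealthState.STEMI


def test_annualize_maps_years_and_death():
    s = annualize(
        [
            rec("a", date(2010, 3, 1), "I20.0", death=date(2012, 1, 20)),
            rec("a", date(2011, 5, 1), "I21.2", death=date(2012, 1, 20)),
        ]
    )
    kinds = [(o.time_years, o.kind) for o in s.observations]
    assert kinds[0] == (0.0, "observed")
    assert s.observations[0].state is HealthState.WELL
    assert kinds[1] == (1.0, "observed")
    assert s.observations[1].state is HealthState.STEMI
    assert s.observations[2].kind == "death"
    assert 2.0 < s.observations[2].time_years < 2.1


def test_excluded_mi_only_year_becomes_censored():
    s = annualize(
        [
            rec("a", date(2010, 2, 1), "I20.0"),
            rec("a", date(2011, 7, 1), "I21.9"),
            rec("a", date(2012, 7, 1), "I21.4"),
        ]
    )
    assert [o.kind for o in s.observations] == ["observed", "censored", "observed"]


def test_single_admission_degenerate_series():
    s = annualize([rec("a", date(2012, 2, 1), "I21.4")])
    assert len(s.observations) == 1
    assert s.observations[0].state is HealthState.NSTEMI


# ---------------------------------------------------------------------------
# add_censored_rows
# ---------------------------------------------------------------------------


def test_gap_years_get_censored_rows():
    s = make_series([(0, 0), (3, 1)])
    out = add_censored_rows(s)
    assert [(o.time_years, o.kind) for o in out.observations] == [
        (0.0, "observed"),
        (1.0, "censored"),
        (2.0, "censored"),
        (3.0, "observed"),
    ]


def test_consecutive_years_unchanged():
    s = make_series([(0, 0), (1, 1), (2, 2)])
    assert add_censored_rows(s).observations == s.observations


def test_censored_rows_before_fractional_death_time():
    s = make_series([(0, 1)], death_time=3.4)
    out = add_censored_rows(s)
    times = [(o.time_years, o.kind) for o in out.observations]
    assert times == [
        (0.0, "observed"),
        (1.0, "censored"),
        (2.0, "censored"),
        (3.0, "censored"),
        (3.4, "death"),
    ]


def test_gap_fraction_on_ten_patient_fixture():
    """7 of 10 patients have gaps -> fraction with added rows is 0.7."""
    cohort = []
    for i in range(7):
        cohort.append(make_series([(0, 0), (2 + (i % 2), 1)], patient_id=f"g{i}"))
    for i in range(3):
        cohort.append(make_series([(0, 0), (1, 1)], patient_id=f"n{i}"))
    augmented = [add_censored_rows(s) for s in cohort]
    grew = [len(a.observations) > len(s.observations) for a, s in zip(augmented, cohort)]
    assert sum(grew) / len(grew) == 0.7


@settings(max_examples=100, derandomize=True)
@given(
    st.lists(
        st.integers(min_value=1, max_value=4), min_size=1, max_size=6
    ),
    st.integers(min_value=0, max_value=2),
)
def test_row_conservation_property(gaps, s0):
    """Rows after augmentation = rows before + total gap years."""
    times = [0]
    for g in gaps:
        times.append(times[-1] + g)
    s = make_series([(t, (s0 + i) % 3 if (s0 + i) % 3 <= 2 else 2) for i, t in enumerate(times)])
    # forward-consistency not required for the conservation property
    out = add_censored_rows(s)
    assert len(out.observations) == len(s.observations) + gap_years(s)
    observed = [o for o in out.observations if o.kind == "observed"]
    assert observed == [o for o in s.observations if o.kind == "observed"]


# ---------------------------------------------------------------------------
# build_cohort filters
# ---------------------------------------------------------------------------


def test_no_mi_patient_excluded():
    series, log = build_cohort(
        [
            rec("a", date(2010, 1, 5), "I20.0"),
            rec("a", date(2012, 1, 5), "I20.0"),
        ]
    )
    assert series == []
    assert log.n_dropped_no_mi == 1


def test_angina_index_with_later_mi_retained_baseline_well():
    series, _ = build_cohort(
        [
            rec("a", date(2010, 1, 5), "I20.0"),
            rec("a", date(2012, 1, 5), "I21.4"),
        ]
    )
    assert len(series) == 1
    assert series[0].observations[0].state is HealthState.WELL
    # gap year 2011 picked up as censored
    assert [o.kind for o in series[0].observations] == [
        "observed",
        "censored",
        "observed",
    ]


def test_five_patient_fixture_filters():
    """5 synthetic patients, 2 lacking MI -> 3 output series."""
    records = [
        rec("p1", date(2010, 1, 5), "I21.4"),
        rec("p2", date(2010, 1, 5), "I20.0"),
        rec("p2", date(2011, 1, 5), "I21.2"),
        rec("p3", date(2010, 1, 5), "I20.0"),  # angina only
        rec("p4", date(2010, 1, 5), "I25.1"),  # other CVD only
        rec("p5", date(2010, 1, 5), "I21.1"),
    ]
    series, log = build_cohort(records)
    assert {s.patient_id for s in series} == {"p1", "p2", "p5"}
    assert log.n_dropped_no_mi == 2


def test_not_first_ever_patient_dropped():
    series, log = build_cohort([rec("a", date(2010, 1, 5), "I21.4", first=False)])
    assert series == []
    assert log.n_dropped_not_first_ever == 1


def test_noncvd_index_admission_dropped():
    series, log = build_cohort(
        [
            rec("a", date(2010, 1, 5), "N17.9"),
            rec("a", date(2011, 1, 5), "I21.4"),
        ]
    )
    assert series == []
    assert log.n_dropped_noncvd_index == 1


def test_missing_covariate_record_rejected_not_fatal():
    records = [
        rec("a", date(2010, 1, 5), "I21.4"),
        AdmissionRecord("a", date(2011, 2, 1), "I20.0", 71, "", "no"),
    ]
    series, log = build_cohort(records)
    assert log.n_records_rejected == 1
    assert len(series) == 1
    assert len(series[0].observations) == 1  # rejected row contributed nothing


def test_tiny_fixture_hand_trace():
    series, log = build_cohort(tiny_cohort())
    assert log.n_patients_in == 5
    assert log.n_series_out == 3
    assert log.n_dropped_no_mi == 1
    assert log.n_dropped_not_first_ever == 1
    assert log.n_records_rejected == 1
    by_id = {s.patient_id: s for s in series}
    assert set(by_id) == {"T1", "T4", "T5"}
    assert by_id["T4"].observations[0].state is HealthState.STEMI
    assert by_id["T4"].died


# ---------------------------------------------------------------------------
# series validation and CSV round-trips
# ---------------------------------------------------------------------------


def test_series_invariants_enforced():
    with pytest.raises(ValueError):
        PatientSeries("x", 0, 0, 60, [Observation(0.0, "censored")]).validate()
    with pytest.raises(ValueError):
        PatientSeries(
            "x",
            0,
            0,
            60,
            [
                Observation(0.0, "observed", HealthState.WELL),
                Observation(0.0, "observed", HealthState.WELL),
            ],
        ).validate()


def test_series_frame_round_trip(small_cohort):
    series, _ = small_cohort
    df = series_to_frame(series)
    back = frame_to_series(df)
    key = lambda s: s.patient_id
    for a, b in zip(sorted(series, key=key), sorted(back, key=key)):
        assert a.patient_id == b.patient_id
        assert (a.sex, a.indigenous, a.baseline_age) == (b.sex, b.indigenous, b.baseline_age)
        assert a.observations == b.observations


def test_admissions_csv_round_trip(tmp_path):
    from mihmm.cohort import admissions_to_frame

    records = tiny_cohort()
    path = tmp_path / "adm.csv"
    admissions_to_frame(records).to_csv(path, index=False)
    back = read_admissions_csv(path)
    assert back == records
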