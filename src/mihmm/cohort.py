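"""Cohort construction: raw admission records -> annualized observation series.

The pipeline mirrors how a panel-observed multistate analysis is prepared
from linked hospital admission data:

1. records with missing covariates are rejected (counted in the build log);
2. patients whose first-ever admission predates the study window are dropped
   (``first_ever`` flag — left-censoring control);
3. patients whose index admission's primary diagnosis is not cardiovascular
   are dropped;
4. patients with no NSTEMI/STEMI admission are dropped (MI sub-cohort);
5. admissions are annualized — one observation per calendar year, taking the
   most severe state seen that year — and death is appended at its exact
   time in years since baseline;
6. censored rows are inserted for gap years with no admission, so the
   likelihood can marginalize over the unknown live state in those years.

Unspecified-MI admissions (I21.9/I21.A) are dropped as events; a year
containing only such admissions contributes a censored row.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date
from typing import Iterable, Optional, Sequence

import math

import numpy as np
import pandas as pd

from .states import (
    CLASS_TO_STATE,
    HealthState,
    ICDClass,
    MI_CLASSES,
    classify_icd10,
    is_cvd_code,
)

STUDY_START = date(2010, 1, 1)
STUDY_END = date(2015, 12, 31)

DAYS_PER_YEAR = 365.25

KIND_OBSERVED = "observed"
KIND_CENSORED = "censored"
KIND_DEATH = "death"


@dataclass(frozen=True)
class AdmissionRecord:
    """One hospital admission row."""

    patient_id: str
    admission_date: date
    icd10_primary: str
    age_at_admission: int
    sex: str  # "male" / "female"
    indigenous: str  # "yes" / "no"
    first_ever: bool = True
    death_date: Optional[date] = None

    def validate(self) -> None:
        if not (STUDY_START <= self.admission_date <= STUDY_END):
            raise ValueError(
                f"admission_date {self.admission_date} outside study window"
            )
        if self.death_date is not None and self.death_date < self.admission_date:
            raise ValueError("death_date precedes admission_date")
        if self.age_at_admission < 0:
            raise ValueError("age must be non-negative")


@dataclass(frozen=True)
class Observation:
    """One row of a patient's annualized series."""

    time_years: float
    kind: str  # observed / censored / death
    state: Optional[HealthState] = None  # set only when kind == observed


@dataclass
class PatientSeries:
    """A patient's annualized observation sequence with covariates.

    ``sex`` is coded male=1, female=0; ``indigenous`` Indigenous=1.
    ``baseline_age`` is integer age at the index admission; age at later
    times is ``baseline_age + floor(t)`` (integer yearly updates).
    """

    patient_id: str
    sex: int
    indigenous: int
    baseline_age: int
    observations: list[Observation] = field(default_factory=list)

    def validate(self) -> None:
        obs = self.observations
        if not obs:
            raise ValueError("series has no observations")
        if obs[0].kind != KIND_OBSERVED or obs[0].state is None:
            raise ValueError("first observation must be an observed state")
        if obs[0].state == HealthState.DEAD:
            raise ValueError("baseline state cannot be DEAD")
        times = [o.time_years for o in obs]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("observation times must be strictly increasing")
        deaths = [i for i, o in enumerate(obs) if o.kind == KIND_DEATH]
        if deaths and deaths != [len(obs) - 1]:
            raise ValueError("death entry must be unique and last")
        for o in obs:
            if o.kind == KIND_OBSERVED and o.state is None:
                raise ValueError("observed entry lacks a state")
            if o.kind != KIND_OBSERVED and o.state is not None:
                raise ValueError(f"{o.kind} entry must not carry a state")

    @property
    def died(self) -> bool:
        return bool(self.observations) and self.observations[-1].kind == KIND_DEATH


def _sex_code(sex: str) -> int:
    s = sex.strip().lower()
    if s in ("male", "m", "1"):
        return 1
    if s in ("female", "f", "0"):
        return 0
    raise ValueError(f"unrecognized sex value: {sex!r}")


def _yes_no(v: str) -> int:
    s = str(v).strip().lower()
    if s in ("yes", "y", "true", "1"):
        return 1
    if s in ("no", "n", "false", "0"):
        return 0
    raise ValueError(f"unrecognized yes/no value: {v!r}")


def annualize(admissions: Sequence[AdmissionRecord]) -> PatientSeries:
    """Collapse one patient's admissions to one observation per calendar year.

    Within a year the most severe state wins (WELL < NSTEMI < STEMI).
    Years whose only admissions are excluded-MI codes become censored rows
    (unless they precede the first real observation, in which case they are
    dropped — a series must open with an observed state). Death, if present,
    is appended at its exact fractional time in years since the baseline
    year's start.
    """
    if not admissions:
        raise ValueError("annualize requires at least one admission")
    adms = sorted(admissions, key=lambda r: r.admission_date)

    by_year: dict[int, list[AdmissionRecord]] = {}
    for r in adms:
        by_year.setdefault(r.admission_date.year, []).append(r)

    year_state: dict[int, Optional[HealthState]] = {}
    for year, rows in by_year.items():
        states = []
        for r in rows:
            cls = classify_icd10(r.icd10_primary)
            if cls is ICDClass.EXCLUDED_MI:
                continue
            states.append(CLASS_TO_STATE[cls])
        year_state[year] = max(states) if states else None  # None -> censored

    # baseline = first year with a real (non-excluded) state
    years = sorted(year_state)
    base_candidates = [y for y in years if year_state[y] is not None]
    if not base_candidates:
        raise ValueError("patient has no admissions with a usable state")
    y0 = base_candidates[0]
    first = next(r for r in adms if r.admission_date.year == y0)

    obs: list[Observation] = []
    for y in years:
        if y < y0:
            continue
        st = year_state[y]
        if st is None:
            obs.append(Observation(float(y - y0), KIND_CENSORED))
        else:
            obs.append(Observation(float(y - y0), KIND_OBSERVED, st))

    death = adms[0].death_date
    if death is not None:
        t = (death - date(y0, 1, 1)).days / DAYS_PER_YEAR
        # registry death on the day of an admission: nudge forward one day
        # so times stay strictly increasing
        if obs and t <= obs[-1].time_years:
            t = obs[-1].time_years + 1.0 / DAYS_PER_YEAR
        obs.append(Observation(t, KIND_DEATH))

    series = PatientSeries(
        patient_id=first.patient_id,
        sex=_sex_code(first.sex),
        indigenous=_yes_no(first.indigenous),
        baseline_age=int(first.age_at_admission),
        observations=obs,
    )
    series.validate()
    return series


def gap_years(series: PatientSeries) -> int:
    """Number of integer years strictly between consecutive observations."""
    total = 0
    times = [o.time_years for o in series.observations]
    for t1, t2 in zip(times, times[1:]):
        lo = math.floor(t1) + 1
        hi = math.ceil(t2) - 1  # integers strictly below t2
        if t2 == math.floor(t2):
            hi = int(t2) - 1
        total += max(0, hi - lo + 1)
    return total


def add_censored_rows(series: PatientSeries) -> PatientSeries:
    """Insert a censored row at every gap year between observations.

    A patient with admissions in 2010 and 2013 gets censored rows for 2011
    and 2012: their state in those years is known only to be one of the
    live states. The death row counts as an observation for gap-filling
    (the patient is provably alive at whole years before the death time),
    which also keeps every likelihood interval at most one year long.
    """
    out: list[Observation] = []
    obs = series.observations
    for o1, o2 in zip(obs, obs[1:]):
        out.append(o1)
        y = math.floor(o1.time_years) + 1
        while y < o2.time_years:
            out.append(Observation(float(y), KIND_CENSORED))
            y += 1
    out.append(obs[-1])
    new = replace(series, observations=out)
    new.validate()
    return new


@dataclass
class CohortBuildLog:
    """Counts emitted by :func:`build_cohort`, for the run log."""

    n_records_in: int = 0
    n_records_rejected: int = 0
    n_patients_in: int = 0
    n_dropped_not_first_ever: int = 0
    n_dropped_noncvd_index: int = 0
    n_dropped_no_mi: int = 0
    n_series_out: int = 0
    n_censored_rows_added: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def build_cohort(
    records: Iterable[AdmissionRecord],
    require_mi: bool = True,
) -> tuple[list[PatientSeries], CohortBuildLog]:
    """Apply the cohort filters and return annualized, gap-augmented series.

    Parameters
    ----------
    records : iterable of AdmissionRecord
    require_mi : bool
        Keep only patients with at least one NSTEMI/STEMI admission
        (the MI sub-cohort definition). Recovery experiments on simulated
        cohorts set this to False, because conditioning on an observed MI
        is an ascertainment filter relative to the generating process.
    """
    log = CohortBuildLog()
    clean: dict[str, list[AdmissionRecord]] = {}
    for r in records:
        log.n_records_in += 1
        try:
            r.validate()
            _sex_code(r.sex)
            _yes_no(r.indigenous)
            classify_icd10(r.icd10_primary)
            if r.age_at_admission is None:
                raise ValueError("missing age")
        except (ValueError, TypeError, AttributeError):
            log.n_records_rejected += 1
            continue
        clean.setdefault(r.patient_id, []).append(r)

    log.n_patients_in = len(clean)
    out: list[PatientSeries] = []
    for pid in sorted(clean):
        adms = sorted(clean[pid], key=lambda r: r.admission_date)
        if not adms[0].first_ever:
            log.n_dropped_not_first_ever += 1
            continue
        if not is_cvd_code(adms[0].icd10_primary):
            log.n_dropped_noncvd_index += 1
            continue
        has_mi = any(
            classify_icd10(r.icd10_primary) in MI_CLASSES for r in adms
        )
        if require_mi and not has_mi:
            log.n_dropped_no_mi += 1
            continue
        try:
            series = annualize(adms)
        except ValueError:
            log.n_records_rejected += len(adms)
            continue
        before = len(series.observations)
        series = add_censored_rows(series)
        log.n_censored_rows_added += len(series.observations) - before
        out.append(series)
    log.n_series_out = len(out)
    return out, log


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

ADMISSIONS_COLUMNS = [
    "patient_id",
    "admission_date",
    "icd10_primary",
    "age",
    "sex",
    "indigenous",
    "first_ever",
    "death_date",
]

SERIES_COLUMNS = [
    "patient_id",
    "time_years",
    "kind",
    "state",
    "age",
    "sex",
    "indigenous",
]


def read_admissions_csv(path) -> list[AdmissionRecord]:
    """Read the canonical admissions CSV (empty death_date = alive)."""
    df = pd.read_csv(path, dtype={"patient_id": str}, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        death = getattr(row, "death_date", "")
        records.append(
            AdmissionRecord(
                patient_id=str(row.patient_id),
                admission_date=date.fromisoformat(str(row.admission_date)),
                icd10_primary=str(row.icd10_primary),
                age_at_admission=int(row.age) if str(row.age) != "" else None,
                sex=str(row.sex),
                indigenous=str(row.indigenous),
                first_ever=bool(_yes_no(str(row.first_ever))),
                death_date=date.fromisoformat(str(death)) if str(death) else None,
            )
        )
    return records


def admissions_to_frame(records: Sequence[AdmissionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "admission_date": r.admission_date.isoformat(),
                "icd10_primary": r.icd10_primary,
                "age": r.age_at_admission,
                "sex": r.sex,
                "indigenous": r.indigenous,
                "first_ever": "yes" if r.first_ever else "no",
                "death_date": r.death_date.isoformat() if r.death_date else "",
            }
        )
    return pd.DataFrame(rows, columns=ADMISSIONS_COLUMNS)


def series_to_frame(series_list: Sequence[PatientSeries]) -> pd.DataFrame:
    """Long-format frame: one row per observation."""
    rows = []
    for s in series_list:
        for o in s.observations:
            rows.append(
                {
                    "patient_id": s.patient_id,
                    "time_years": o.time_years,
                    "kind": o.kind,
                    "state": o.state.name if o.state is not None else "",
                    "age": s.baseline_age + int(math.floor(o.time_years)),
                    "sex": "male" if s.sex else "female",
                    "indigenous": "yes" if s.indigenous else "no",
                }
            )
    return pd.DataFrame(rows, columns=SERIES_COLUMNS)


def frame_to_series(df: pd.DataFrame) -> list[PatientSeries]:
    """Inverse of :func:`series_to_frame`."""
    out = []
    for pid, g in df.groupby("patient_id", sort=True):
        g = g.sort_values("time_years")
        first = g.iloc[0]
        obs = []
        for row in g.itertuples(index=False):
            state = (
                HealthState[row.state]
                if isinstance(row.state, str) and row.state
                else None
            )
            obs.append(Observation(float(row.time_years), str(row.kind), state))
        s = PatientSeries(
            patient_id=str(pid),
            sex=_sex_code(str(first["sex"])),
            indigenous=_yes_no(str(first["indigenous"])),
            baseline_age=int(first["age"]) - int(math.floor(float(first["time_years"]))),
            observations=obs,
        )
        s.validate()
        out.append(s)
    return out


def write_series_csv(series_list: Sequence[PatientSeries], path) -> None:
    series_to_frame(series_list).to_csv(path, index=False)


def read_series_csv(path) -> list[PatientSeries]:
    df = pd.read_csv(path, dtype={"patient_id": str}, keep_default_na=False)
    df["state"] = df["state"].astype(str)
    return frame_to_series(df)
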