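"""Synthetic admission-record cohorts with the model's exact structure.

The generator reads the model generatively: each patient's true state
follows the forward-only continuous-time Markov chain (competing
exponential clocks per state, re-drawn at yearly age boundaries so
intensities are piecewise-constant in integer age), entered at the index
admission in the first study year. The observation process emulates
annual hospital contact: the baseline year is always observed; each later
live year produces an admission with probability ``1 - gap_probability``;
the recorded ICD-10 code is drawn through the misclassification matrix
applied to the true state at that year boundary; death emits an exact
death date. The emitted CSV round-trips through the cohort pipeline.

Default "truth" parameters are of the magnitude published for elderly
Australian MI cohorts (reference profile: female, non-Indigenous, age 67),
so simulated output is realistic in scale. By default the baseline
observation is recorded without misclassification, matching the model's
assumption that the analysis conditions on the baseline state as true
(set ``baseline_misclassification=True`` to break that assumption).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .cohort import DAYS_PER_YEAR, AdmissionRecord, admissions_to_frame
from .intensity import transition_rates
from .params import DEFAULT_AGE_CENTER, ProgressionParams
from .states import HealthState

# q1..q6 at the reference profile (female, non-Indigenous, mean age 67),
# per-year intensities of published magnitude for an MI admission cohort
_REF_RATES = np.array([0.0846, 0.0129, 0.0282, 0.0242, 0.0508, 0.0464])
# multiplicative sex (male) and ethnicity (Indigenous) effects, as rate ratios
_SEX_RATIOS = np.array([8.70 / 8.46, 1.92 / 1.29, 2.83 / 2.82,
                        2.43 / 2.42, 5.12 / 5.08, 4.68 / 4.64])
_ETH_RATIOS = np.array([8.62 / 8.61, 1.68 / 1.69, 2.81 / 2.83,
                        2.41 / 2.43, 5.10 / 5.11, 4.68 / 4.66])
# per-year relative-risk increase with age: ~1.5% for STEMI entry,
# ~3% for death transitions, near-flat for NSTEMI entry
_AGE_RATIOS = np.array([1.002, 1.015, 1.03, 1.015, 1.03, 1.03])

DEFAULT_EMISSIONS = np.array([0.011, 0.037, 0.015, 0.027])

WELL_CODES = ("I20.0", "I25.1", "I48.0", "I50.0")
STEMI_CODES = ("I21.0", "I21.1", "I21.2", "I21.3")


def default_true_params() -> ProgressionParams:
    """Generating truth of realistic magnitude for an MI cohort."""
    beta = np.column_stack(
        [
            np.log(_REF_RATES),
            np.log(_AGE_RATIOS),
            np.log(_SEX_RATIOS),
            np.log(_ETH_RATIOS),
        ]
    )
    return ProgressionParams(beta=beta, e=DEFAULT_EMISSIONS.copy())


@dataclass
class SimConfig:
    """Study conditions for a simulated cohort (defaults mirror the design
    of a 2010-indexed, six-wave admission cohort)."""

    n_patients: int
    seed: int
    follow_up_years: int = 6
    params: ProgressionParams = field(default_factory=default_true_params)
    male_fraction: float = 0.6
    indigenous_fraction: float = 0.039
    age_mean: float = 67.0
    age_sd: float = 12.0
    age_range: tuple[int, int] = (18, 100)
    baseline_state_probs: tuple[float, float, float] = (0.60, 0.28, 0.12)
    gap_probability: float = 0.3
    baseline_misclassification: bool = False
    start_year: int = 2010
    age_center: float = DEFAULT_AGE_CENTER

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for f in (self.male_fraction, self.indigenous_fraction, self.gap_probability):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(self.baseline_state_probs) - 1) > 1e-9:
            raise ValueError("baseline_state_probs must sum to 1")


def simulate_trajectory(
    params: ProgressionParams,
    covariates: tuple[int, int, int],  # (baseline age, sex, ethnicity)
    horizon: float,
    rng: np.random.Generator,
    start_state: HealthState = HealthState.WELL,
    age_center: float = DEFAULT_AGE_CENTER,
) -> list[tuple[float, HealthState]]:
    """One true continuous-time path: [(time, state entered at time), ...].

    Competing exponentials per current state; clocks are re-drawn at every
    integer year boundary, where the patient's age advances by one year
    (memorylessness makes the re-draw exact). Forward-only; stops at DEAD
    or at the horizon.
    """
    age0, sex, eth = covariates
    t = 0.0
    state = HealthState(start_state)
    path = [(0.0, state)]
    while t < horizon and state != HealthState.DEAD:
        age = age0 + int(np.floor(t))
        q = transition_rates(params, age, sex, eth, age_center)
        if state == HealthState.WELL:
            rates = {HealthState.NSTEMI: q[0], HealthState.STEMI: q[1],
                     HealthState.DEAD: q[2]}
        elif state == HealthState.NSTEMI:
            rates = {HealthState.STEMI: q[3], HealthState.DEAD: q[4]}
        else:  # STEMI
            rates = {HealthState.DEAD: q[5]}
        total = sum(rates.values())
        boundary = np.floor(t) + 1.0
        if total <= 0:
            t = boundary
            continue
        wait = rng.exponential(1.0 / total)
        if t + wait >= min(boundary, horizon):
            t = min(boundary, horizon)  # no event before age update / horizon
            continue
        t = t + wait
        dests = list(rates)
        probs = np.array([rates[d] for d in dests]) / total
        state = dests[rng.choice(len(dests), p=probs)]
        path.append((t, state))
    return path


def state_at(path: Sequence[tuple[float, HealthState]], t: float) -> HealthState:
    """State occupied at time t (right-continuous)."""
    current = path[0][1]
    for time, st in path:
        if time <= t:
            current = st
        else:
            break
    return current


def death_time(path: Sequence[tuple[float, HealthState]]) -> Optional[float]:
    for time, st in path:
        if st == HealthState.DEAD:
            return time
    return None


def _observed_state(
    true_state: HealthState, e: np.ndarray, rng: np.random.Generator
) -> HealthState:
    r = rng.random()
    if true_state == HealthState.WELL:
        return HealthState.NSTEMI if r < e[0] else HealthState.WELL
    if true_state == HealthState.NSTEMI:
        if r < e[1]:
            return HealthState.WELL
        if r < e[1] + e[2]:
            return HealthState.STEMI
        return HealthState.NSTEMI
    if true_state == HealthState.STEMI:
        return HealthState.NSTEMI if r < e[3] else HealthState.STEMI
    return HealthState.DEAD


def _code_for(state: HealthState, rng: np.random.Generator) -> str:
    if state == HealthState.WELL:
        return WELL_CODES[rng.integers(len(WELL_CODES))]
    if state == HealthState.NSTEMI:
        return "I21.4"
    if state == HealthState.STEMI:
        return STEMI_CODES[rng.integers(len(STEMI_CODES))]
    raise ValueError("DEAD emits no admission")


def observe_cohort(
    true_paths: Sequence[list[tuple[float, HealthState]]],
    covariates: Sequence[tuple[int, int, int]],
    params: ProgressionParams,
    config: SimConfig,
    rng: np.random.Generator,
    patient_ids: Optional[Sequence[str]] = None,
) -> list[AdmissionRecord]:
    """Turn true paths into admission records via the observation process."""
    records: list[AdmissionRecord] = []
    e = params.e
    for i, (path, (age0, sex, eth)) in enumerate(zip(true_paths, covariates)):
        pid = patient_ids[i] if patient_ids else f"P{i + 1:06d}"
        t_death = death_time(path)
        dd = None
        if t_death is not None:
            dd = date(config.start_year, 1, 1) + timedelta(
                days=int(round(t_death * DAYS_PER_YEAR))
            )
        last_live_year = (
            config.follow_up_years - 1
            if t_death is None
            else min(int(np.floor(t_death)), config.follow_up_years - 1)
        )
        for k in range(last_live_year + 1):
            if t_death is not None and t_death <= k:
                break
            if k > 0 and rng.random() < config.gap_probability:
                continue  # gap year: alive, no admission
            true_k = state_at(path, float(k))
            if true_k == HealthState.DEAD:
                continue
            if k == 0 and not config.baseline_misclassification:
                obs_state = true_k
            else:
                obs_state = _observed_state(true_k, e, rng)
            # admission day within calendar year, before death if same year
            max_day = 350
            if t_death is not None and int(np.floor(t_death)) == k:
                max_day = max(1, int((t_death - k) * DAYS_PER_YEAR) - 1)
            day = int(rng.integers(0, max_day)) if max_day > 1 else 0
            records.append(
                AdmissionRecord(
                    patient_id=pid,
                    admission_date=date(config.start_year + k, 1, 1)
                    + timedelta(days=day),
                    icd10_primary=_code_for(obs_state, rng),
                    age_at_admission=age0 + k,
                    sex="male" if sex else "female",
                    indigenous="yes" if eth else "no",
                    first_ever=True,
                    death_date=dd,
                )
            )
    return records


def simulate_cohort(config: SimConfig) -> list[AdmissionRecord]:
    """Full generative run: covariates -> true paths -> admission records."""
    rng = np.random.default_rng(config.seed)
    params = config.params
    paths = []
    covs = []
    lo, hi = config.age_range
    for _ in range(config.n_patients):
        sex = int(rng.random() < config.male_fraction)
        eth = int(rng.random() < config.indigenous_fraction)
        age0 = int(np.clip(round(rng.normal(config.age_mean, config.age_sd)), lo, hi))
        s0 = HealthState(rng.choice(3, p=np.asarray(config.baseline_state_probs)))
        covs.append((age0, sex, eth))
        paths.append(
            simulate_trajectory(
                params,
                (age0, sex, eth),
                float(config.follow_up_years),
                rng,
                start_state=s0,
                age_center=config.age_center,
            )
        )
    return observe_cohort(paths, covs, params, config, rng)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


def tiny_cohort() -> list[AdmissionRecord]:
    """Five handwritten patients exercising the pipeline's branches.

    T1: angina index 2010, NSTEMI 2012 (gap year 2011)        -> retained
    T2: angina admissions only (no MI)                        -> excluded
    T3: first_ever = no, NSTEMI 2010                          -> excluded
    T4: NSTEMI + STEMI within 2010 (severity rule), dies 2012;
        one extra 2011 row with a missing covariate, rejected -> retained
    T5: angina 2010, I21.9-only year 2011 (censored), STEMI 2013 -> retained
    """
    mk = AdmissionRecord
    return [
        mk("T1", date(2010, 3, 1), "I20.0", 70, "female", "no"),
        mk("T1", date(2012, 6, 1), "I21.4", 72, "female", "no"),
        mk("T2", date(2010, 4, 1), "I20.0", 60, "male", "no"),
        mk("T2", date(2013, 5, 1), "I20.0", 63, "male", "no"),
        mk("T3", date(2010, 2, 1), "I21.4", 55, "male", "yes", first_ever=False),
        mk("T4", date(2010, 3, 10), "I21.4", 80, "male", "no",
           death_date=date(2012, 8, 15)),
        mk("T4", date(2010, 9, 20), "I21.2", 80, "male", "no",
           death_date=date(2012, 8, 15)),
        mk("T4", date(2011, 4, 2), "", 81, "male", "no",
           death_date=date(2012, 8, 15)),  # missing code: rejected record
        mk("T5", date(2010, 7, 1), "I20.0", 66, "female", "no"),
        mk("T5", date(2011, 8, 1), "I21.9", 67, "female", "no"),
        mk("T5", date(2013, 2, 1), "I21.1", 69, "female", "no"),
    ]


FIXTURE_SCALES = {"tiny": None, "test": 500, "full": 8705}


def make_fixture(scale: str, out_dir, seed: int = 1) -> Path:
    """Write an admissions CSV fixture; returns its path.

    ``tiny``: the 5 handwritten patients; ``test``: n=500 simulated;
    ``full``: n=8705 patients (the published cohort size) over 6 annual
    waves with the default published-magnitude truth.
    """
    if scale not in FIXTURE_SCALES:
        raise ValueError(f"unknown scale {scale!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"admissions_{scale}.csv"
    if scale == "tiny":
        records = tiny_cohort()
    else:
        records = simulate_cohort(
            SimConfig(n_patients=FIXTURE_SCALES[scale], seed=seed)
        )
    admissions_to_frame(records).to_csv(path, index=False)
    return path
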