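import numpy as np
import pytest

from mihmm.cohort import Observation, PatientSeries, build_cohort
from mihmm.params import ProgressionParams
from mihmm.simulate import SimConfig, default_true_params, simulate_cohort
from mihmm.states import HealthState


@pytest.fixture(scope="session")
def truth_params() -> ProgressionParams:
    return default_true_params()


@pytest.fixture(scope="session")
def small_cohort(truth_params):
    """n=300 simulated cohort prepared without the MI filter (session-wide)."""
    records = simulate_cohort(SimConfig(n_patients=300, seed=42))
    series, log = build_cohort(records, require_mi=False)
    return series, log


def make_series(
    states,
    patient_id="X",
    sex=0,
    indigenous=0,
    baseline_age=67,
    death_time=None,
):
    """Series from a list of (time, state-or-None); None means censored."""
    obs = []
    for t, s in states:
        if s is None:
            obs.append(Observation(float(t), "censored"))
        else:
            obs.append(Observation(float(t), "observed", HealthState(s)))
    if death_time is not None:
        obs.append(Observation(float(death_time), "death"))
    series = PatientSeries(patient_id, sex, indigenous, baseline_age, obs)
    series.validate()
    return series


def random_params(rng: np.random.Generator) -> ProgressionParams:
    """Random valid parameters of plausible magnitude."""
    beta = np.zeros((6, 4))
    beta[:, 0] = np.log(rng.uniform(0.01, 0.3, 6))
    beta[:, 1] = rng.normal(0.0, 0.02, 6)
    beta[:, 2:] = rng.normal(0.0, 0.1, (6, 2))
    e = rng.uniform(0.005, 0.12, 4)
    return ProgressionParams(beta=beta, e=e)


def random_series(rng: np.random.Generator, max_len: int = 5) -> PatientSeries:
    """Random short series mixing observed, censored and death rows."""
    n = int(rng.integers(2, max_len + 1))
    states = [(0.0, int(rng.integers(0, 3)))]
    t = 0.0
    death = None
    for k in range(n - 1):
        t += float(np.round(rng.uniform(0.3, 1.5), 3))
        if k == n - 2 and rng.random() < 0.35:
            death = t
            break
        if rng.random() < 0.3:
            states.append((t, None))
        else:
            states.append((t, int(rng.integers(0, 3))))
    return make_series(
        states,
        sex=int(rng.integers(2)),
        indigenous=int(rng.integers(2)),
        baseline_age=int(rng.integers(45, 90)),
        death_time=death,
    )
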