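"""Forward-algorithm log-likelihood for annualized patient series.

The model is a hidden Markov chain: the true state follows a forward-only
continuous-time Markov chain whose generator is rebuilt at each interval
boundary using the patient's current integer age (piecewise-constant
intensities within a year); observed states are emitted with
misclassification. The baseline observed state is taken as the true state
with probability one — the analysis conditions on the state at first
hospitalization, which is also how delayed enrolment is handled.

Censored rows contribute a weight of 1 over the live states (the patient
was alive but not admitted). A death row contributes, by default, the
exact death-time density: transition over the interval to any live state
followed by an instantaneous death jump,

    sum_i alpha_i * sum_j P(dt)[i, j] * q_{j,DEAD} .

The interval-censored alternative (death known only to occur within the
interval) is available with ``death_mode="interval"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from ._kernels import cohort_loglik_kernel
from .cohort import KIND_CENSORED, KIND_DEATH, KIND_OBSERVED, PatientSeries
from .intensity import build_emission, build_Q, transition_probability, transition_rates
from .params import DEFAULT_AGE_CENTER, ProgressionParams
from .states import HealthState

_KIND_CODE = {KIND_OBSERVED: 0, KIND_CENSORED: 1, KIND_DEATH: 2}


def series_loglik(
    series: PatientSeries,
    params: ProgressionParams,
    age_center: float = DEFAULT_AGE_CENTER,
    death_mode: str = "exact",
    baseline_emission: bool = False,
) -> float:
    """Log-likelihood of one patient series (reference implementation).

    Plain numpy/scipy version, kept deliberately close to the recursion as
    written mathematically; :func:`cohort_loglik` runs the same computation
    through a compiled kernel. An impossible sequence (zero likelihood
    under the forward-only structure) returns ``-inf``, never raises.

    With ``baseline_emission=True`` the baseline observation is treated as
    misclassified too, starting from a uniform prior over live states
    (off by default; the standard analysis conditions on the baseline).
    """
    if death_mode not in ("exact", "interval"):
        raise ValueError("death_mode must be 'exact' or 'interval'")
    series.validate()
    params.validate()
    E = build_emission(params)

    obs0 = series.observations[0]
    alpha = np.zeros(3)
    if baseline_emission:
        alpha[:] = E[:3, obs0.state] / 3.0
    else:
        alpha[obs0.state] = 1.0
    logscale = 0.0

    t_prev = obs0.time_years
    for o in series.observations[1:]:
        dt = o.time_years - t_prev
        age = series.baseline_age + math.floor(t_prev)
        Q = build_Q(params, age, series.sex, series.indigenous, age_center)
        P = transition_probability(Q, dt)
        if o.kind == KIND_DEATH:
            if death_mode == "exact":
                q = transition_rates(
                    params, age, series.sex, series.indigenous, age_center
                )
                qd = np.array([q[2], q[4], q[5]])
                val = float(alpha @ (P[:3, :3] @ qd))
            else:
                val = float(alpha @ P[:3, 3])
            alpha = np.array([val, 0.0, 0.0])
        else:
            alpha = alpha @ P[:3, :3]
            if o.kind == KIND_OBSERVED:
                alpha = alpha * E[:3, o.state]
        total = float(alpha.sum())
        if not np.isfinite(total) or total <= 0.0:
            return -np.inf
        alpha /= total
        logscale += math.log(total)
        t_prev = o.time_years
    return logscale


@dataclass
class CohortData:
    """Patient series packed into flat arrays for the compiled kernel.

    Intervals sharing a (centered age, sex, ethnicity, dt) profile share
    one matrix exponential; ``Xu``/``dtu`` hold the unique profiles and
    ``pidx`` indexes into them per patient step.
    """

    Xu: np.ndarray       # (U, 3)
    dtu: np.ndarray      # (U,)
    s0: np.ndarray       # (n,)
    kind: np.ndarray     # (n, K)
    obs: np.ndarray      # (n, K)
    pidx: np.ndarray     # (n, K)
    nsteps: np.ndarray   # (n,)
    age_center: float

    @property
    def n_patients(self) -> int:
        return int(self.s0.shape[0])

    @property
    def n_observations(self) -> int:
        return int(self.nsteps.sum() + self.n_patients)

    @classmethod
    def from_series(
        cls,
        series_list: Sequence[PatientSeries],
        age_center: float = DEFAULT_AGE_CENTER,
    ) -> "CohortData":
        if not series_list:
            raise ValueError("empty series list")
        n = len(series_list)
        K = max(len(s.observations) - 1 for s in series_list)
        K = max(K, 1)
        kind = np.zeros((n, K), dtype=np.int8)
        obs = np.zeros((n, K), dtype=np.int8)
        pidx = np.zeros((n, K), dtype=np.int32)
        nsteps = np.zeros(n, dtype=np.int32)
        s0 = np.zeros(n, dtype=np.int8)
        profiles: dict[tuple, int] = {}
        Xu_rows: list[tuple] = []
        dtu_rows: list[float] = []
        for p, s in enumerate(series_list):
            s.validate()
            s0[p] = int(s.observations[0].state)
            t_prev = s.observations[0].time_years
            for k, o in enumerate(s.observations[1:]):
                dt = o.time_years - t_prev
                age_c = s.baseline_age + math.floor(t_prev) - age_center
                key = (age_c, s.sex, s.indigenous, round(dt, 9))
                u = profiles.get(key)
                if u is None:
                    u = len(Xu_rows)
                    profiles[key] = u
                    Xu_rows.append((age_c, float(s.sex), float(s.indigenous)))
                    dtu_rows.append(dt)
                pidx[p, k] = u
                kind[p, k] = _KIND_CODE[o.kind]
                obs[p, k] = int(o.state) if o.state is not None else 0
                t_prev = o.time_years
            nsteps[p] = len(s.observations) - 1
        return cls(
            Xu=np.array(Xu_rows, dtype=float).reshape(len(Xu_rows), 3),
            dtu=np.array(dtu_rows, dtype=float),
            s0=s0,
            kind=kind,
            obs=obs,
            pidx=pidx,
            nsteps=nsteps,
            age_center=age_center,
        )


def cohort_loglik(
    data: Union[CohortData, Sequence[PatientSeries]],
    params: ProgressionParams,
    age_center: float = DEFAULT_AGE_CENTER,
    death_mode: str = "exact",
) -> float:
    """Sum of per-patient log-likelihoods (order-invariant).

    Accepts either a packed :class:`CohortData` or a list of series.
    """
    if death_mode not in ("exact", "interval"):
        raise ValueError("death_mode must be 'exact' or 'interval'")
    if not isinstance(data, CohortData):
        if len(data) == 0:
            raise ValueError("empty series list")
        data = CohortData.from_series(data, age_center)
    params.validate()
    return float(
        cohort_loglik_kernel(
            np.ascontiguousarray(params.beta, dtype=float),
            np.ascontiguousarray(params.e, dtype=float),
            data.Xu,
            data.dtu,
            data.s0,
            data.kind,
            data.obs,
            data.pidx,
            data.nsteps,
            death_mode == "exact",
        )
    )
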