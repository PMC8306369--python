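"""Independent oracles used by the test suite.

The path-enumeration likelihood sums explicitly over every assignment of
hidden live states, using the public matrix-probability surface (scipy's
expm); it shares no code with the forward recursion it checks.
"""

import itertools
import math

from mihmm.cohort import KIND_CENSORED, KIND_DEATH, KIND_OBSERVED, PatientSeries
from mihmm.intensity import (
    build_emission,
    build_Q,
    transition_probability,
    transition_rates,
)
from mihmm.params import DEFAULT_AGE_CENTER, ProgressionParams

LIVE = (0, 1, 2)


def enumeration_loglik(
    series: PatientSeries,
    params: ProgressionParams,
    age_center: float = DEFAULT_AGE_CENTER,
) -> float:
    """Brute-force hidden-path likelihood (exponential in series length)."""
    obs = series.observations
    E = build_emission(params)
    s0 = int(obs[0].state)
    steps = obs[1:]

    # per-step transition matrices and death intensities at interval start
    mats = []
    t_prev = obs[0].time_years
    for o in steps:
        dt = o.time_years - t_prev
        age = series.baseline_age + math.floor(t_prev)
        Q = build_Q(params, age, series.sex, series.indigenous, age_center)
        P = transition_probability(Q, dt)
        q = transition_rates(params, age, series.sex, series.indigenous, age_center)
        mats.append((P, (q[2], q[4], q[5])))
        t_prev = o.time_years

    n_hidden = sum(1 for o in steps if o.kind != KIND_DEATH)
    total = 0.0
    for assign in itertools.product(LIVE, repeat=n_hidden):
        prob = 1.0
        prev = s0
        ai = 0
        for o, (P, qd) in zip(steps, mats):
            if o.kind == KIND_DEATH:
                prob *= sum(P[prev, j] * qd[j] for j in LIVE)
            else:
                h = assign[ai]
                ai += 1
                prob *= P[prev, h]
                if o.kind == KIND_OBSERVED:
                    prob *= E[h, int(o.state)]
                prev = h
            if prob == 0.0:
                break
        total += prob
    return math.log(total) if total > 0.0 else float("-inf")
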