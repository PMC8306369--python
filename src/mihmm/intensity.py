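"""Generator (Q), transition-probability and emission matrices.

The continuous-time Markov chain over (WELL, NSTEMI, STEMI, DEAD) is
forward-only: its generator is upper triangular with zero row sums and a
zero DEAD row. Transition probabilities over an interval of length t are
P(t) = expm(t Q). The misclassification (emission) matrix E gives
P(observed | true); only the four adjacent-state channels carry error,
and DEAD is observed without error.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from .params import DEFAULT_AGE_CENTER, ProgressionParams

#: (row, col) cell of Q for each transition q1..q6
Q_CELLS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


def transition_rates(
    params: ProgressionParams,
    age: float,
    sex: int,
    ethnicity: int,
    age_center: float = DEFAULT_AGE_CENTER,
) -> np.ndarray:
    """The six intensities q1..q6 at a covariate profile.

    ``age`` is in years; it is centered at ``age_center`` internally, so
    intercepts are interpreted at the cohort mean age.
    """
    x = np.array([1.0, age - age_center, float(sex), float(ethnicity)])
    with np.errstate(over="ignore"):
        q = np.exp(params.beta @ x)
    if not np.all(np.isfinite(q)):
        raise ValueError("non-finite transition intensity")
    return q


def build_Q(
    params: ProgressionParams,
    age: float,
    sex: int,
    ethnicity: int,
    age_center: float = DEFAULT_AGE_CENTER,
) -> np.ndarray:
    """The 4x4 generator at a covariate profile (rows sum to zero)."""
    q = transition_rates(params, age, sex, ethnicity, age_center)
    return q_to_matrix(q)


def q_to_matrix(q) -> np.ndarray:
    """Place intensities q1..q6 into the forward-only generator."""
    q = np.asarray(q, dtype=float)
    Q = np.zeros((4, 4))
    for l, (i, j) in enumerate(Q_CELLS):
        Q[i, j] = q[l]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def transition_probability(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(t Q), the interval transition-probability matrix."""
    if t < 0:
        raise ValueError("elapsed time t must be non-negative")
    Q = np.asarray(Q, dtype=float)
    P = scipy.linalg.expm(t * Q)
    # clip tiny negative round-off; rows remain stochastic to ~1e-15
    return np.clip(P, 0.0, 1.0)


def build_emission(params: ProgressionParams) -> np.ndarray:
    """The 4x4 row-stochastic misclassification matrix E[true, observed].

    Rows: true WELL (1-e1, e1, 0, 0); true NSTEMI (e2, 1-e2-e3, e3, 0);
    true STEMI (0, e4, 1-e4, 0); true DEAD (0, 0, 0, 1). With all e at the
    zero boundary E is the identity and the model degenerates to an
    ordinary (fully observed) panel Markov model.
    """
    params.validate()
    e1, e2, e3, e4 = params.e
    return np.array(
        [
            [1 - e1, e1, 0.0, 0.0],
            [e2, 1 - e2 - e3, e3, 0.0],
            [0.0, e4, 1 - e4, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
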