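"""Model parameters: transition-intensity coefficients and misclassification.

Six forward transitions are modelled, each with a log-linear intensity

    log q_l = b0_l + b1_l * (age - age_center) + b2_l * sex + b3_l * indigenous

(sex male=1, Indigenous=1; age centered at the cohort mean, 67 by default),
plus four misclassification probabilities:

    e1 = P(obs NSTEMI | true WELL)
    e2 = P(obs WELL   | true NSTEMI)
    e3 = P(obs STEMI  | true NSTEMI)
    e4 = P(obs NSTEMI | true STEMI)

Each e is bounded in [0, 0.5): the upper bound is an identifiability guard
(label switching) standard for misclassification HMMs; 0 is allowed and
turns the model into an ordinary panel-observed Markov model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .states import HealthState

#: transition index -> (from, to); order defines q1..q6
TRANSITIONS = (
    (HealthState.WELL, HealthState.NSTEMI),
    (HealthState.WELL, HealthState.STEMI),
    (HealthState.WELL, HealthState.DEAD),
    (HealthState.NSTEMI, HealthState.STEMI),
    (HealthState.NSTEMI, HealthState.DEAD),
    (HealthState.STEMI, HealthState.DEAD),
)

TRANSITION_LABELS = tuple(
    f"{a.name} -> {b.name}" for a, b in TRANSITIONS
)

COVARIATES = ("intercept", "age", "sex", "ethnicity")

N_TRANSITIONS = len(TRANSITIONS)
N_COVARIATES = len(COVARIATES)
N_EMISSION = 4

#: flat parameter names in canonical order (24 betas then e1..e4)
PARAM_NAMES = tuple(
    f"q{l + 1}.{c}" for l in range(N_TRANSITIONS) for c in COVARIATES
) + tuple(f"e{k + 1}" for k in range(N_EMISSION))

DEFAULT_AGE_CENTER = 67.0


@dataclass
class ProgressionParams:
    """All model parameters: beta (6 x 4) and e (4,)."""

    beta: np.ndarray
    e: np.ndarray

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.e = np.asarray(self.e, dtype=float)
        if self.beta.shape != (N_TRANSITIONS, N_COVARIATES):
            raise ValueError(
                f"beta must have shape {(N_TRANSITIONS, N_COVARIATES)}"
            )
        if self.e.shape != (N_EMISSION,):
            raise ValueError("e must have shape (4,)")

    def validate(self) -> None:
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta must be finite")
        if np.any(self.e < 0) or np.any(self.e >= 0.5):
            raise ValueError("misclassification probabilities must lie in [0, 0.5)")
        if self.e[1] + self.e[2] >= 1:
            raise ValueError("e2 + e3 must be < 1")

    # -- flat vector (natural scale) ------------------------------------
    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.beta.ravel(), self.e])

    @classmethod
    def from_vector(cls, v) -> "ProgressionParams":
        v = np.asarray(v, dtype=float)
        if v.shape != (N_TRANSITIONS * N_COVARIATES + N_EMISSION,):
            raise ValueError("parameter vector has wrong length")
        return cls(
            beta=v[: N_TRANSITIONS * N_COVARIATES].reshape(
                N_TRANSITIONS, N_COVARIATES
            ),
            e=v[N_TRANSITIONS * N_COVARIATES :].copy(),
        )

    # -- flat key/value config ------------------------------------------
    def to_dict(self) -> dict:
        out = {}
        for l in range(N_TRANSITIONS):
            for c, name in enumerate(COVARIATES):
                out[f"beta.q{l + 1}.{name}"] = float(self.beta[l, c])
        for k in range(N_EMISSION):
            out[f"emission.e{k + 1}"] = float(self.e[k])
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ProgressionParams":
        beta = np.zeros((N_TRANSITIONS, N_COVARIATES))
        e = np.zeros(N_EMISSION)
        for l in range(N_TRANSITIONS):
            for c, name in enumerate(COVARIATES):
                beta[l, c] = float(d[f"beta.q{l + 1}.{name}"])
        for k in range(N_EMISSION):
            e[k] = float(d[f"emission.e{k + 1}"])
        return cls(beta=beta, e=e)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ProgressionParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def copy(self) -> "ProgressionParams":
        return ProgressionParams(beta=self.beta.copy(), e=self.e.copy())
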