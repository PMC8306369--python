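"""Derived report quantities: per-profile rate tables, MI risk sums,
age relative-risk arithmetic and the misclassification prevalence
correction.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence, Union

import numpy as np
import pandas as pd

from .inference import PosteriorSummary
from .params import DEFAULT_AGE_CENTER, TRANSITION_LABELS, ProgressionParams
from .intensity import transition_rates
from .states import HealthState

#: default report profiles: vary one covariate, hold the other at the
#: cohort mode (male, non-Indigenous), age at the cohort mean
DEFAULT_PROFILES = (
    {"name": "Males", "sex": 1, "ethnicity": 0, "age": DEFAULT_AGE_CENTER},
    {"name": "Females", "sex": 0, "ethnicity": 0, "age": DEFAULT_AGE_CENTER},
    {"name": "Indigenous", "sex": 1, "ethnicity": 1, "age": DEFAULT_AGE_CENTER},
    {"name": "Non-Indigenous", "sex": 1, "ethnicity": 0, "age": DEFAULT_AGE_CENTER},
)

_PROFILE_FIELDS = {"name", "sex", "ethnicity", "age"}


def _params_of(source: Union[PosteriorSummary, ProgressionParams]) -> ProgressionParams:
    if isinstance(source, PosteriorSummary):
        return source.params_mean
    return source


def transition_table(
    source: Union[PosteriorSummary, ProgressionParams],
    profiles: Sequence[dict] = DEFAULT_PROFILES,
    age_center: float = DEFAULT_AGE_CENTER,
) -> pd.DataFrame:
    """Six posterior-mean transition rates (percent) per covariate profile.

    Entries are ``exp`` of the posterior-mean linear predictor at each
    profile, expressed as per-year percentages; full precision is kept in
    the frame (render with ``.round(2)`` for a 2-decimal table).
    """
    params = _params_of(source)
    cols = {}
    for prof in profiles:
        unknown = set(prof) - _PROFILE_FIELDS
        if unknown:
            raise ValueError(f"unknown profile fields: {sorted(unknown)}")
        q = transition_rates(
            params, prof["age"], prof["sex"], prof["ethnicity"], age_center
        )
        cols[prof.get("name", f"sex={prof['sex']},eth={prof['ethnicity']}")] = q * 100
    return pd.DataFrame(cols, index=list(TRANSITION_LABELS))


def state_risk(rates, target: HealthState) -> float:
    """Risk of entering the target MI state: the sum of its entry rates.

    ``rates`` is the 6-vector (q1..q6) in any linear unit (the result is in
    the same unit). risk(STEMI) = q2 + q4 (from WELL and from NSTEMI);
    risk(NSTEMI) = q1 (direct entry). Only MI states are reportable.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (6,):
        raise ValueError("rates must be the 6 transition rates q1..q6")
    target = HealthState(target)
    if target == HealthState.STEMI:
        return float(rates[1] + rates[3])
    if target == HealthState.NSTEMI:
        return float(rates[0])
    raise ValueError("state_risk is defined for NSTEMI and STEMI only")


class AgeRelativeRisk(NamedTuple):
    linear: float
    compounded: float


def age_relative_risk_linear(per_year_increase: float, years: float) -> AgeRelativeRisk:
    """Relative-risk change over an age gap.

    ``linear`` is the simple ``years * per_year_increase`` approximation
    (e.g. a 1.5%/year increase over 40 years ~ 60%); ``compounded`` is the
    exact multiplicative value ``(1 + r)^years - 1`` for comparison
    (1.015^40 - 1 ~ 81.4%).
    """
    if not (np.isfinite(per_year_increase) and np.isfinite(years)):
        raise ValueError("inputs must be finite")
    linear = years * per_year_increase
    compounded = (1.0 + per_year_increase) ** years - 1.0
    return AgeRelativeRisk(linear=float(linear), compounded=float(compounded))


def prevalence_correction(e1: float, e2: float, e3: float, e4: float) -> tuple[float, float]:
    """Net upward corrections to NSTEMI and STEMI prevalence implied by
    the misclassification probabilities (flow accounting of under-counts):

        dNSTEMI = (e2 + e3) - (e1 + e4)   (true NSTEMIs recorded elsewhere,
                                           minus non-NSTEMIs recorded as NSTEMI)
        dSTEMI  = e4 - e3                 (STEMIs recorded as NSTEMI minus
                                           NSTEMIs recorded as STEMI)

    The two satisfy dNSTEMI + dSTEMI = e2 - e1 identically. Returned in the
    same unit as the inputs (probabilities in, probabilities out).
    """
    d_nstemi = (e2 + e3) - (e1 + e4)
    d_stemi = e4 - e3
    return float(d_nstemi), float(d_stemi)


def misclassification_table(summary: PosteriorSummary) -> pd.DataFrame:
    """Four misclassification channels with posterior mean and 95% set."""
    labels = [
        ("NSTEMI", "Well"),
        ("Well", "NSTEMI"),
        ("STEMI", "NSTEMI"),
        ("NSTEMI", "STEMI"),
    ]
    rows = []
    for k, (obs, true) in enumerate(labels):
        name = f"e{k + 1}"
        lo, hi = summary.credible_interval(name)
        rows.append(
            {
                "observed": obs,
                "true": true,
                "mean": float(summary.table.loc[name, "mean"]),
                "q2.5": lo,
                "q97.5": hi,
            }
        )
    return pd.DataFrame(rows)
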