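"""Cohort descriptives: state proportions by group, chi-square tests and
direct age-standardized rates.

The unit of analysis is the person-year observation: every observed row
contributes its state, the death row contributes DEAD, censored rows are
excluded (no state was recorded). Age bands are <55, 55-64, 65-74, 75+,
with age evaluated at the observation time (baseline age + elapsed whole
years).
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .cohort import KIND_DEATH, KIND_OBSERVED, PatientSeries
from .states import HealthState

AGE_BANDS = ((-math.inf, 55), (55, 65), (65, 75), (75, math.inf))
AGE_BAND_LABELS = ("<55", "55-64", "65-74", "75+")

STATE_COLUMNS = tuple(s.name for s in HealthState)

GROUPINGS = ("sex", "ethnicity", "age_group", "none")


def age_band(age: float) -> str:
    for (lo, hi), label in zip(AGE_BANDS, AGE_BAND_LABELS):
        if lo <= age < hi:
            return label
    raise ValueError(f"age {age} outside all bands")


def _observation_table(series_list: Sequence[PatientSeries]) -> pd.DataFrame:
    rows = []
    for s in series_list:
        for o in s.observations:
            if o.kind == KIND_OBSERVED:
                state = o.state
            elif o.kind == KIND_DEATH:
                state = HealthState.DEAD
            else:
                continue
            age = s.baseline_age + math.floor(o.time_years)
            rows.append(
                {
                    "state": state.name,
                    "sex": "Males" if s.sex else "Females",
                    "ethnicity": "Indigenous" if s.indigenous else "Non-Indigenous",
                    "age_group": age_band(age),
                }
            )
    return pd.DataFrame(rows)


def state_counts(
    series_list: Sequence[PatientSeries], grouping: str = "none"
) -> pd.DataFrame:
    """Person-year observation counts per group x state."""
    if grouping not in GROUPINGS:
        raise ValueError(f"grouping must be one of {GROUPINGS}")
    obs = _observation_table(series_list)
    if obs.empty:
        raise ValueError("no person-year observations")
    if grouping == "none":
        obs = obs.assign(_group="All cases")
        key = "_group"
    else:
        key = grouping
    counts = (
        obs.groupby(key)["state"].value_counts().unstack(fill_value=0)
    )
    for c in STATE_COLUMNS:
        if c not in counts.columns:
            counts[c] = 0
    counts = counts[list(STATE_COLUMNS)]
    counts.index.name = "group"
    return counts


def state_proportions(
    series_list: Sequence[PatientSeries], grouping: str = "none"
) -> tuple[pd.DataFrame, Optional[float]]:
    """Row-normalized state proportions per group, plus a chi-square p-value.

    The Pearson chi-square (no continuity correction) is computed on the
    underlying count table when there are >= 2 non-empty groups; groups with
    zero observations are excluded with a warning. With a single group the
    p-value is None.
    """
    counts = state_counts(series_list, grouping)
    empty = counts.index[counts.sum(axis=1) == 0]
    if len(empty):
        import warnings

        warnings.warn(f"groups with zero observations excluded: {list(empty)}")
        counts = counts.drop(index=empty)
    props = counts.div(counts.sum(axis=1), axis=0)
    pvalue = None
    if counts.shape[0] >= 2:
        # drop all-zero state columns to keep the statistic well-defined
        tab = counts.loc[:, counts.sum(axis=0) > 0].to_numpy()
        stat, pvalue, _, _ = scipy.stats.chi2_contingency(tab, correction=False)
        pvalue = float(pvalue)
    return props, pvalue


def age_standardize(
    group_rates_by_stratum: pd.DataFrame, standard_weights: pd.Series
) -> pd.Series:
    """Directly standardized rate per group.

    ``group_rates_by_stratum``: rows = groups, columns = age strata;
    ``standard_weights``: weight per stratum, summing to one and aligned
    with the columns.
    """
    weights = pd.Series(standard_weights, dtype=float)
    if set(weights.index) != set(group_rates_by_stratum.columns):
        raise ValueError("strata of weights and rates do not align")
    if abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError("standard weights must sum to 1")
    weights = weights.reindex(group_rates_by_stratum.columns)
    return (group_rates_by_stratum * weights).sum(axis=1)


def age_standardized_state_rates(
    series_list: Sequence[PatientSeries],
    grouping: str,
    state: HealthState,
) -> pd.Series:
    """State-occupancy rate per group, standardized to the pooled cohort
    age distribution (internal standard)."""
    if grouping not in ("sex", "ethnicity"):
        raise ValueError("standardize by 'sex' or 'ethnicity'")
    obs = _observation_table(series_list)
    if obs.empty:
        raise ValueError("no person-year observations")
    weights = obs["age_group"].value_counts(normalize=True)
    obs["hit"] = (obs["state"] == HealthState(state).name).astype(float)
    rates = obs.pivot_table(
        index=grouping, columns="age_group", values="hit", aggfunc="mean"
    ).fillna(0.0)
    weights = weights.reindex(rates.columns).fillna(0.0)
    weights = weights / weights.sum()
    return age_standardize(rates, weights)
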