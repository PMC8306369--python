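"""Model and results objects for the MI-progression hidden Markov model.

``MIProgressionModel`` wraps a prepared cohort (annualized, censoring-
augmented patient series) together with the prior; ``fit`` runs the
blockwise Metropolis sampler and returns an ``MIProgressionResults``
carrying the posterior draws, credible sets, diagnostics and the derived
report tables.

Typical use::

    series, log = build_cohort(read_admissions_csv("admissions.csv"))
    model = MIProgressionModel(series)
    res = model.fit(seed=1, chains=2, iterations=4000)
    print(res.summary())
    print(res.transition_table().round(2))
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cohort import PatientSeries, frame_to_series, read_series_csv
from .inference import (
    MCMCChains,
    MCMCConfig,
    PosteriorSummary,
    PriorSpec,
    log_posterior,
    params_to_theta,
    run_mcmc,
    summarize,
)
from .likelihood import CohortData, cohort_loglik
from .params import DEFAULT_AGE_CENTER, PARAM_NAMES, ProgressionParams
from .report import (
    DEFAULT_PROFILES,
    misclassification_table,
    prevalence_correction,
    state_risk,
    transition_table,
)
from .states import HealthState


class MIProgressionModel:
    """Bayesian multistate HMM of MI progression on an admission cohort."""

    def __init__(
        self,
        series: Sequence[PatientSeries],
        prior: Optional[PriorSpec] = None,
        age_center: float = DEFAULT_AGE_CENTER,
    ):
        if len(series) == 0:
            raise ValueError("model requires at least one patient series")
        self.series = list(series)
        self.prior = prior if prior is not None else PriorSpec.default()
        self.age_center = age_center
        self.data = CohortData.from_series(self.series, age_center)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "MIProgressionModel":
        """Build from the canonical long-format series frame."""
        return cls(frame_to_series(df), **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "MIProgressionModel":
        return cls(read_series_csv(path), **kwargs)

    # -- likelihood surface ---------------------------------------------
    def loglike(self, params: ProgressionParams, death_mode: str = "exact") -> float:
        return cohort_loglik(self.data, params, self.age_center, death_mode)

    def logpost(self, params: Union[ProgressionParams, np.ndarray]) -> float:
        theta = (
            params_to_theta(params)
            if isinstance(params, ProgressionParams)
            else np.asarray(params, float)
        )
        return log_posterior(theta, self.data, self.prior)

    # -- fitting ---------------------------------------------------------
    def fit(
        self,
        seed: int,
        chains: int = 4,
        iterations: int = 20_000,
        burn_in: float = 0.5,
        fix_emissions: bool = False,
        compute_ess: bool = True,
        init: Optional[ProgressionParams] = None,
    ) -> "MIProgressionResults":
        config = MCMCConfig(
            seed=seed,
            chains=chains,
            iterations=iterations,
            burn_in=burn_in,
            fix_emissions=fix_emissions,
        )
        theta0 = params_to_theta(init) if init is not None else None
        mcmc = run_mcmc(self.data, self.prior, config, init=theta0)
        summary = summarize(mcmc, compute_ess=compute_ess)
        return MIProgressionResults(self, mcmc, summary)


class MIProgressionResults:
    """Posterior draws, summaries and derived report tables."""

    def __init__(
        self,
        model: MIProgressionModel,
        chains: MCMCChains,
        summary: PosteriorSummary,
    ):
        self.model = model
        self.chains = chains
        self._summary = summary

    # -- estimates -------------------------------------------------------
    @property
    def params(self) -> ProgressionParams:
        """Posterior-mean parameters."""
        return self._summary.params_mean

    @property
    def posterior(self) -> pd.DataFrame:
        """Post-burn-in natural-scale draws, one row per draw."""
        return self.chains.to_frame()

    @property
    def accept_rates(self) -> np.ndarray:
        return self._summary.accept_rates

    def credible_interval(self, name: str) -> tuple[float, float]:
        return self._summary.credible_interval(name)

    def summary(self) -> pd.DataFrame:
        """Per-parameter posterior mean, sd, 95% credible set (and ESS)."""
        return self._summary.table.copy()

    def __repr__(self) -> str:
        tab = self._summary.table
        return (
            f"<MIProgressionResults: {tab.shape[0]} parameters, "
            f"{self._summary.n_draws} draws, "
            f"mean acceptance {float(self.accept_rates.mean()):.2f}>"
        )

    # -- report tables ---------------------------------------------------
    def transition_table(self, profiles=DEFAULT_PROFILES) -> pd.DataFrame:
        return transition_table(self._summary, profiles, self.model.age_center)

    def misclassification_table(self) -> pd.DataFrame:
        return misclassification_table(self._summary)

    def state_risk(self, profile: dict, target: HealthState) -> float:
        """Posterior-mean entry risk (percent) of an MI state at a profile."""
        tab = transition_table(self._summary, [profile], self.model.age_center)
        return state_risk(tab.iloc[:, 0].to_numpy(), target)

    def prevalence_correction(self) -> tuple[float, float]:
        e = self.params.e
        return prevalence_correction(*e)

    # -- persistence / plotting -----------------------------------------
    def save_draws(self, path) -> None:
        self.posterior.to_csv(path, index=False)

    def plot_trace(self, names: Optional[Sequence[str]] = None, axes=None):
        """Trace plots of selected parameters (post burn-in, per chain)."""
        import matplotlib.pyplot as plt

        names = list(names) if names else ["q1.intercept", "e2"]
        if axes is None:
            _, axes = plt.subplots(len(names), 1, figsize=(8, 2.2 * len(names)))
        axes = np.atleast_1d(axes)
        df = self.posterior
        for ax, name in zip(axes, names):
            for c, g in df.groupby("chain"):
                ax.plot(g["draw"], g[name], lw=0.5, label=f"chain {c}")
            ax.set_ylabel(name)
        axes[-1].set_xlabel("draw")
        return axes


def results_from_draws(
    draws: pd.DataFrame, model: Optional[MIProgressionModel] = None
) -> PosteriorSummary:
    """Rebuild a PosteriorSummary from a saved draws CSV/frame.

    Used by the report stage, which may run in a separate process from the
    fit. ESS is not recomputed (chain layout may be lost on disk).
    """
    cols = [c for c in PARAM_NAMES if c in draws.columns]
    if len(cols) != len(PARAM_NAMES):
        missing = set(PARAM_NAMES) - set(cols)
        raise ValueError(f"draws frame missing parameters: {sorted(missing)}")
    pooled = draws[list(PARAM_NAMES)].to_numpy(dtype=float)
    lo, hi = np.percentile(pooled, [2.5, 97.5], axis=0)
    tab = pd.DataFrame(
        {
            "mean": pooled.mean(axis=0),
            "sd": pooled.std(axis=0, ddof=1) if pooled.shape[0] > 1 else 0.0,
            "q2.5": lo,
            "q97.5": hi,
        },
        index=list(PARAM_NAMES),
    )
    return PosteriorSummary(table=tab, accept_rates=np.array([[np.nan]]),
                            n_draws=pooled.shape[0])
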