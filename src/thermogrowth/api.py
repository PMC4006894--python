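"""User-facing model and results classes.

The workflow mirrors the familiar fit-and-summarise pattern:

>>> from thermogrowth import ThermalGrowthModel, simulate
>>> records, truth = simulate.simulate_dataset(simulate.default_config(seed=1))
>>> model = ThermalGrowthModel.from_dataframe(records)
>>> result = model.fit(iterations=20_000, seed=1)
>>> result.summary_table(["dH_star", "dS_star", "T_H", "T_S"])

The model holds the data and the structural choices (grouping, priors);
``fit`` runs the hierarchical MCMC and returns a results object carrying
chains, posterior summaries, convergence diagnostics and the derived
thermodynamic quantities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import derived as _derived
from .inference import PosteriorResult, run_mcmc, two_stage_fit
from .priors import PriorSpec
from .simulate import standardize_rates
from .structures import ModelStructure

__all__ = ["ThermalGrowthModel", "ThermalGrowthResults"]


class ThermalGrowthModel:
    """Hierarchical thermodynamic growth model bound to a dataset.

    Parameters
    ----------
    records : DataFrame
        Columns ``strain_id``, ``temperature_K`` and ``rate_std`` (or
        ``rate_obs``, which is standardised per strain on construction).
        An optional ``group`` column supplies the grouping labels.
    structure : str or ModelStructure
        ``"I"`` pools all strains in one group; ``"labels"`` groups by the
        ``group`` column; or pass any :class:`ModelStructure` (e.g. built
        by thermal allocation for structures IV/V).
    priors : PriorSpec, optional
    """

    def __init__(self, records: pd.DataFrame,
                 structure: ModelStructure | str = "labels",
                 priors: PriorSpec | None = None):
        required = {"strain_id", "temperature_K"}
        if missing := required - set(records.columns):
            raise ValueError(f"records missing columns: {sorted(missing)}")
        if "rate_std" not in records.columns:
            if "rate_obs" not in records.columns:
                raise ValueError("records need a rate_std or rate_obs column")
            records = standardize_rates(records)
        self.records = records.reset_index(drop=True)
        self.priors = priors or PriorSpec()
        strain_ids = sorted(self.records["strain_id"].unique())
        if isinstance(structure, ModelStructure):
            self.structure = structure
        elif structure == "I":
            self.structure = ModelStructure.single_group(strain_ids)
        elif structure == "labels":
            if "group" not in self.records.columns:
                raise ValueError("structure='labels' needs a group column")
            labels = (self.records.drop_duplicates("strain_id")
                      .set_index("strain_id")["group"].to_dict())
            self.structure = ModelStructure.from_labels(labels)
        else:
            raise ValueError(f"unknown structure: {structure!r}")

    @classmethod
    def from_dataframe(cls, records: pd.DataFrame, **kwargs
                       ) -> "ThermalGrowthModel":
        return cls(records, **kwargs)

    @classmethod
    def from_csv(cls, path, units: str = "K", **kwargs) -> "ThermalGrowthModel":
        from .io import read_growth_table

        return cls(read_growth_table(path, units=units), **kwargs)

    def fit(self, iterations: int = 50_000, burn_in: float = 0.5,
            seed: int = 0, two_stage: bool = False, **engine_kwargs
            ) -> "ThermalGrowthResults":
        """Run the hierarchical MCMC and return a results object."""
        if two_stage:
            post = two_stage_fit(self.records, self.structure, self.priors,
                                 iterations, burn_in, seed, **engine_kwargs)
        else:
            post = run_mcmc(self.records, self.structure, self.priors,
                            iterations, burn_in, seed, **engine_kwargs)
        return ThermalGrowthResults(self, post)


class ThermalGrowthResults:
    """Posterior summaries, diagnostics and derived quantities of a fit."""

    def __init__(self, model: ThermalGrowthModel, posterior: PosteriorResult):
        self.model = model
        self.posterior = posterior

    # delegated surface -----------------------------------------------------

    def __getattr__(self, name):
        return getattr(self.posterior, name)

    def summary(self, level: float | None = None) -> pd.DataFrame:
        return self.posterior.summary(level)

    def summary_table(self, names=None, level=None, digits: int = 1
                      ) -> pd.DataFrame:
        return self.posterior.summary_table(names, level, digits)

    # derived quantities ----------------------------------------------------

    def derived_table(self) -> pd.DataFrame:
        """Derived-temperature table for each group's posterior-mean
        parameters (stability, optimum and 50%-denaturation bounds)."""
        u = self.posterior.universal_params()
        return _derived.derived_table(u, self.posterior.group_params())

    def native_state_curves(self, T_grid=None) -> pd.DataFrame:
        u = self.posterior.universal_params()
        return _derived.native_state_curve_table(
            u, self.posterior.group_params(), T_grid)

    # plots ------------------------------------------------------------------

    def plot_trace(self, names=None, ax=None):
        """Trace plots of selected chains (diagnostic quality only)."""
        import matplotlib.pyplot as plt

        names = list(names) if names else ["dH_star", "dS_star", "T_H", "T_S"]
        fig, axes = plt.subplots(len(names), 1, figsize=(7, 1.8 * len(names)),
                                 sharex=True, squeeze=False)
        for ax_, name in zip(axes[:, 0], names):
            ax_.plot(self.posterior.chains[name], lw=0.4)
            ax_.set_ylabel(name)
        axes[-1, 0].set_xlabel("iteration")
        fig.tight_layout()
        return fig

    def plot_fit(self, strain_id: str, ax=None):
        """Observed standardised rates and the fitted curve for one strain."""
        import matplotlib.pyplot as plt

        from .model import growth_rate

        if ax is None:
            _, ax = plt.subplots()
        rec = self.model.records
        sub = rec[rec["strain_id"] == strain_id]
        u = self.posterior.universal_params()
        s = self.posterior.strain_params()[strain_id]
        grid = np.linspace(sub["temperature_K"].min() - 3,
                           sub["temperature_K"].max() + 3, 300)
        ax.plot(grid, growth_rate(grid, u, s), label="fitted")
        ax.plot(sub["temperature_K"], sub["rate_std"], "o", label="observed")
        ax.set_xlabel("temperature (K)")
        ax.set_ylabel("standardised rate")
        ax.set_title(strain_id)
        ax.legend()
        return ax
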