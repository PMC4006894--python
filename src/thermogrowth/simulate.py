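"""Synthetic growth-rate datasets with the structure of literature compilations.

Real compilations of intrinsic growth rates pool hundreds of strains, each
observed at a handful of temperatures spanning its biokinetic range, with
rates standardised to a per-strain maximum of one.  The generator emulates
that structure: strains fall into five thermal groups, strain-level enzyme
parameters are Gaussian around group means (truncated at zero), each strain
is observed at ``points_per_strain`` temperatures across its biokinetic
range, and observation noise is Gaussian on the square-root rate scale —
the error model under which the data are later fitted.

The shipped defaults generate 14 strains (2/6/2/2/2 across the groups,
mesophiles most abundant as in real compilations) at 14 temperatures each
— 196 records, matching the record density of a large compilation (~14.3
records per strain).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import GROUP_ORDER, GROUP_REFERENCE, UNIVERSAL_REFERENCE
from .derived import half_denaturation_bounds, optimal_temperature
from .model import StrainParams, UniversalParams, growth_rate, log_growth_rate

__all__ = [
    "GroupSpec",
    "SimulationConfig",
    "draw_strain",
    "biokinetic_grid",
    "simulate_dataset",
    "standardize_rates",
    "default_config",
]

# observable temperature window of the emulated compilation, K
_T_MIN, _T_MAX = 271.0, 396.0


@dataclass(frozen=True)
class GroupSpec:
    """Generating distribution of one thermal group."""

    name: str
    dH_act_mean: float     # J/mol
    dCp_mean: float        # J/(K mol-residue)
    n_mean: float          # residues
    n_strains: int = 2
    dH_act_sd: float = 2000.0
    dCp_sd: float = 1.0
    n_sd: float = 15.0

    def __post_init__(self) -> None:
        if self.n_strains <= 0:
            raise ValueError("n_strains must be positive")
        for name in ("dH_act_sd", "dCp_sd", "n_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a synthetic compilation."""

    groups: tuple[GroupSpec, ...]
    universal: UniversalParams
    points_per_strain: int = 14
    noise_sd: float = 0.02        # SD on the sqrt(rate) scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.points_per_strain < 3:
            raise ValueError("points_per_strain must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def default_config(seed: int = 0, noise_sd: float = 0.02,
                   points_per_strain: int = 14,
                   strains_per_group: dict[str, int] | None = None,
                   ) -> SimulationConfig:
    """Default five-group configuration built from the reference parameters."""
    counts = {"psychrophile": 2, "mesophile": 6, "ascomycota": 2,
              "thermophile": 2, "hyperthermophile": 2}
    if strains_per_group:
        counts.update(strains_per_group)
    groups = tuple(
        GroupSpec(name=g, dH_act_mean=GROUP_REFERENCE[g]["dH_act"],
                  dCp_mean=GROUP_REFERENCE[g]["dCp"], n_mean=GROUP_REFERENCE[g]["n"],
                  n_strains=counts[g])
        for g in GROUP_ORDER if counts[g] > 0
    )
    return SimulationConfig(groups=groups, universal=UniversalParams(**UNIVERSAL_REFERENCE),
                            points_per_strain=points_per_strain,
                            noise_sd=noise_sd, seed=seed)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lower: float = 0.0) -> float:
    """Draw N(mean, sd) truncated to (lower, inf) by simple rejection."""
    if sd == 0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > lower:
            return float(x)
    raise RuntimeError("truncated normal rejection failed; check the group spec")


def draw_strain(group_spec: GroupSpec, rng: np.random.Generator,
                c: float = 1.0) -> StrainParams:
    """Draw one strain's enzyme parameters from its group distribution.

    Gaussian around the group means, truncated at zero so every draw is
    physical.  ``sd = 0`` returns the mean exactly.  ``c`` is a placeholder;
    the simulator rescales it so the modelled maximum rate is one.
    """
    return StrainParams(
        c=c,
        dH_act=_truncated_normal(rng, group_spec.dH_act_mean, group_spec.dH_act_sd),
        dCp=_truncated_normal(rng, group_spec.dCp_mean, group_spec.dCp_sd),
        n=_truncated_normal(rng, group_spec.n_mean, group_spec.n_sd),
        group=group_spec.name,
    )


def biokinetic_grid(s: StrainParams, u: UniversalParams, k: int) -> np.ndarray:
    """``k`` observation temperatures spanning the strain's biokinetic range.

    The grid runs from the cold-side temperature where the modelled rate
    falls to 5% of its maximum up to just past the upper 50%-denaturation
    temperature, clipped to the observable window, and always contains a
    point at the growth optimum.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    t_opt, _ = optimal_temperature(u, s)
    lr_max = log_growth_rate(t_opt, u, s)
    # cold endpoint: rate = 5% of max (bisection; log rate is monotone below T_opt)
    target = lr_max + np.log(0.05)
    lo, hi = 200.0, t_opt
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if log_growth_rate(mid, u, s) < target:
            lo = mid
        else:
            hi = mid
    t_cold = 0.5 * (lo + hi)
    _, t_u = half_denaturation_bounds(u, s.dCp)
    t_hot = (t_u if np.isfinite(t_u) else t_opt) + 2.0
    t_cold = float(np.clip(t_cold, _T_MIN, _T_MAX))
    t_hot = float(np.clip(t_hot, t_cold + 1.0, _T_MAX))
    grid = np.linspace(t_cold, t_hot, k - 1)
    grid = np.unique(np.append(grid, np.clip(t_opt, t_cold, t_hot)))
    # if T_opt coincided with a grid point, pad to keep exactly k temperatures
    while len(grid) < k:
        grid = np.unique(np.append(grid, 0.5 * (grid[-2] + grid[-1])))
    return grid


def simulate_dataset(cfg: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a synthetic compilation and its ground truth.

    Observation model: ``rate_obs = max(0, sqrt(r_model) + eps)**2`` with
    ``eps ~ N(0, noise_sd^2)``; negative perturbed square roots are floored
    at zero since rates are physically non-negative.  Deterministic given
    ``cfg.seed``.

    Returns
    -------
    records : DataFrame
        Columns ``strain_id, group, temperature_K, rate_obs, rate_std``.
    truth : dict
        Generating universal parameters, per-strain parameters and the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    u = cfg.universal
    rows = []
    truth_strains = {}
    idx = 0
    for spec in cfg.groups:
        for _ in range(spec.n_strains):
            idx += 1
            sid = f"{spec.name[:4]}_{idx:03d}"
            s = draw_strain(spec, rng)
            t_opt, _ = optimal_temperature(u, s)
            r_max = growth_rate(t_opt, u, s)
            s = s.with_c(s.c / r_max)  # modelled maximum rate = 1
            grid = biokinetic_grid(s, u, cfg.points_per_strain)
            r_model = growth_rate(grid, u, s)
            sqrt_obs = np.sqrt(r_model) + rng.normal(0.0, cfg.noise_sd, size=len(grid))
            rate_obs = np.maximum(sqrt_obs, 0.0) ** 2
            for T, r in zip(grid, rate_obs):
                rows.append((sid, spec.name, float(T), float(r)))
            truth_strains[sid] = {"c": s.c, "dH_act": s.dH_act, "dCp": s.dCp,
                                  "n": s.n, "group": s.group, "T_opt": t_opt}
    records = pd.DataFrame(rows, columns=["strain_id", "group", "temperature_K", "rate_obs"])
    records = standardize_rates(records)
    truth = {
        "seed": cfg.seed,
        "noise_sd": cfg.noise_sd,
        "universal": {"dH_star": u.dH_star, "dS_star": u.dS_star,
                      "T_H": u.T_H, "T_S": u.T_S},
        "strains": truth_strains,
        "group_means": {g.name: {"dH_act": g.dH_act_mean, "dCp": g.dCp_mean,
                                 "n": g.n_mean} for g in cfg.groups},
    }
    return records, truth


def standardize_rates(records: pd.DataFrame, rate_col: str = "rate_obs") -> pd.DataFrame:
    """Add/refresh ``rate_std``: rates divided by each strain's maximum.

    Idempotent; preserves within-strain rate ordering.  Raises if any
    strain has no positive rate (standardisation undefined).
    """
    out = records.copy()
    gmax = out.groupby("strain_id")[rate_col].transform("max")
    bad = out.loc[gmax <= 0, "strain_id"].unique()
    if len(bad):
        raise ValueError(f"strains with no positive rate: {', '.join(map(str, bad))}")
    out["rate_std"] = out[rate_col] / gmax
    return out


def write_dataset(records: pd.DataFrame, truth: dict, csv_path, json_path) -> None:
    """Write the records CSV and the companion ground-truth JSON."""
    cols = ["strain_id", "group", "temperature_K", "rate_obs", "rate_std"]
    records[[c for c in cols if c in records.columns]].to_csv(csv_path, index=False)
    with open(json_path, "w") as fh:
        json.dump(truth, fh, indent=1)
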