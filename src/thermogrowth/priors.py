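"""Prior specification for the hierarchical model.

Universal unfolding parameters and thermal/taxonomic group means carry
uniform priors with limits informed by the protein-biochemistry
literature; strain-level enzyme parameters are Gaussian around their group
means with per-parameter-type precisions ``tau_theta`` (themselves uniform
on a wide interval); the observational precision on the square-root rate
scale is gamma; and the scaling constant ``c`` is sampled on the log scale
with a wide (vague but proper) uniform prior.

The growth curves are exactly invariant under jointly rescaling
``(dH_star, dS_star, dCp)`` by a constant and dividing every residue
count ``n`` by the same constant — the free energy is homogeneous of
degree one in the first three and enters the model only as ``n * dG``.
The absolute scale of the unfolding thermodynamics is therefore fixed by
the prior, not by growth data: the default bounds on the universal
parameters are deliberately informative, bracketing the published
convergence-temperature estimates for globular proteins.

All densities are proper and fully normalised so that marginal likelihoods
of competing group structures are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

__all__ = ["PriorSpec"]

#: strain/group parameter types that carry the hierarchical Gaussian prior
HIER_PARAMS = ("dH_act", "dCp", "n")


def _ordered(bounds: dict[str, tuple[float, float]], label: str) -> None:
    for k, (lo, hi) in bounds.items():
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"{label} bounds for {k} must be finite and ordered")


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of every prior in the hierarchical model.

    Units: ``dH_act`` J/mol, ``dCp`` J/(K·mol-residue), ``n`` residues,
    ``dH_star`` J/mol-residue, ``dS_star`` J/(K·mol-residue), temperatures K.
    ``tau_theta_bounds`` are on the precisions (1/variance) of the
    between-strain Gaussians; ``gamma_obs`` is (shape, rate) of the gamma
    prior on the observational precision.
    """

    universal_bounds: dict = field(default_factory=lambda: {
        "dH_star": (4600.0, 5200.0),
        "dS_star": (16.0, 18.5),
        "T_H": (371.0, 379.0),
        "T_S": (386.0, 394.0),
    })
    group_bounds: dict = field(default_factory=lambda: {
        "dH_act": (20e3, 200e3),
        "dCp": (20.0, 120.0),
        "n": (50.0, 1000.0),
    })
    log_c_bounds: tuple = (-10.0, 60.0)
    tau_theta_bounds: dict = field(default_factory=lambda: {
        "dH_act": (1e-10, 1e-2),
        "dCp": (1e-4, 1e2),
        "n": (1e-7, 1.0),
    })
    gamma_obs: tuple = (0.001, 0.001)

    def __post_init__(self) -> None:
        _ordered(self.universal_bounds, "universal")
        _ordered(self.group_bounds, "group")
        _ordered(self.tau_theta_bounds, "tau_theta")
        lo, hi = self.log_c_bounds
        if not lo < hi:
            raise ValueError("log_c bounds must be ordered")
        a, b = self.gamma_obs
        if not (a > 0 and b > 0):
            raise ValueError("gamma hyperparameters must be positive")

    # -- evaluation helpers -------------------------------------------------

    def universal_midpoint(self) -> np.ndarray:
        b = self.universal_bounds
        return np.array([(b[k][0] + b[k][1]) / 2
                         for k in ("dH_star", "dS_star", "T_H", "T_S")])

    def group_midpoint(self) -> np.ndarray:
        b = self.group_bounds
        return np.array([(b[k][0] + b[k][1]) / 2 for k in HIER_PARAMS])

    def log_uniform_universal(self, u_vec: np.ndarray) -> float:
        """Normalised uniform-box density of the universal parameter vector."""
        total = 0.0
        for x, k in zip(u_vec, ("dH_star", "dS_star", "T_H", "T_S")):
            lo, hi = self.universal_bounds[k]
            if not lo <= x <= hi:
                return -np.inf
            total -= np.log(hi - lo)
        # the model additionally requires T_H < T_S
        if not u_vec[2] < u_vec[3]:
            return -np.inf
        return total

    def log_uniform_group(self, mean_vec: np.ndarray) -> float:
        total = 0.0
        for x, k in zip(mean_vec, HIER_PARAMS):
            lo, hi = self.group_bounds[k]
            if not lo <= x <= hi:
                return -np.inf
            total -= np.log(hi - lo)
        return total

    def log_uniform_log_c(self, log_c) -> float:
        lo, hi = self.log_c_bounds
        log_c = np.atleast_1d(log_c)
        if np.any(log_c < lo) or np.any(log_c > hi):
            return -np.inf
        return -len(log_c) * float(np.log(hi - lo))

    def log_tau_theta_prior(self, tau: np.ndarray) -> float:
        """Uniform (on the precision scale) prior density for tau_theta."""
        total = 0.0
        for x, k in zip(tau, HIER_PARAMS):
            lo, hi = self.tau_theta_bounds[k]
            if not lo <= x <= hi:
                return -np.inf
            total -= np.log(hi - lo)
        return total

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        d = dict(d)
        for key in ("universal_bounds", "group_bounds", "tau_theta_bounds"):
            if key in d:
                d[key] = {k: tuple(v) for k, v in d[key].items()}
        for key in ("log_c_bounds", "gamma_obs"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PriorSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"malformed prior configuration in {path}")
        try:
            return cls.from_dict(raw)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed prior configuration in {path}: {exc}") from exc
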