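"""Core thermodynamic growth-rate model.

The model assumes population growth is limited by a single enzyme-catalysed
reaction.  The rate of the reaction follows an Arrhenius-type law, while the
fraction of the rate-controlling enzyme in its catalytically active (native)
conformation follows a two-state folding equilibrium whose free energy is
parameterised through the convergence temperatures of protein unfolding
(the Murphy–Privalov parameterisation):

    dG(T)   = dH* + dCp (T - T_H) - T [dS* + dCp ln(T / T_S)]
    P_nat(T) = 1 / (1 + exp(-n dG(T) / (R T)))
    r(T)    = c T exp(-dH_act / (R T)) * P_nat(T)

with ``dG`` the per-residue Gibbs energy of unfolding, ``n`` the number of
amino-acid residues of the enzyme, ``dH_act`` the enthalpy of activation of
the catalysed reaction and ``c`` a scaling constant.  ``dG`` is concave in
``T`` (d2G/dT2 = -dCp/T), so the enzyme denatures at both temperature
extremes: the model produces the characteristic asymmetric, unimodal
growth curve observed across psychrophiles to hyperthermophiles.

All temperatures are Kelvin; energies are J/mol (per amino-acid residue for
the unfolding parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .constants import R

__all__ = [
    "UniversalParams",
    "StrainParams",
    "unfolding_free_energy",
    "native_state_probability",
    "growth_rate",
    "log_growth_rate",
]


@dataclass(frozen=True)
class UniversalParams:
    """Protein-unfolding parameters assumed common to all strains.

    Parameters
    ----------
    dH_star : float
        Enthalpy change of unfolding at the enthalpy convergence
        temperature, J per mol amino-acid residue.
    dS_star : float
        Entropy change of unfolding at the entropy convergence
        temperature, J/(K · mol amino-acid residue).
    T_H, T_S : float
        Convergence temperatures for enthalpy and entropy, K.
        For globular proteins ``T_H < T_S``.
    """

    dH_star: float
    dS_star: float
    T_H: float
    T_S: float

    def __post_init__(self) -> None:
        for name in ("dH_star", "dS_star", "T_H", "T_S"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("T_H", "T_S"):
            if not 250.0 < getattr(self, name) < 450.0:
                raise ValueError(f"{name} must lie in (250, 450) K")
        if not self.T_H < self.T_S:
            raise ValueError("convergence temperatures must satisfy T_H < T_S")

    def as_array(self) -> np.ndarray:
        return np.array([self.dH_star, self.dS_star, self.T_H, self.T_S])

    @classmethod
    def from_array(cls, a) -> "UniversalParams":
        return cls(*(float(x) for x in a))


@dataclass(frozen=True)
class StrainParams:
    """Rate-limiting-enzyme parameters of one strain.

    Parameters
    ----------
    c : float
        Scaling constant; carries the units of the rate data (per K).
    dH_act : float
        Enthalpy of activation of the rate-limiting reaction, J/mol.
    dCp : float
        Heat-capacity change on denaturation, J/(K · mol amino-acid residue).
    n : float
        Number of amino-acid residues of the enzyme (continuous-valued).
    group : str
        Thermal- or taxonomic-group label.
    """

    c: float
    dH_act: float
    dCp: float
    n: float
    group: str = ""

    def __post_init__(self) -> None:
        for name in ("c", "dCp"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        # zero is tolerated for dH_act and n as degenerate limiting cases
        for name in ("dH_act", "n"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def with_c(self, c: float) -> "StrainParams":
        return replace(self, c=c)


def _check_temperature(T) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be strictly positive (Kelvin)")
    return T


def unfolding_free_energy(T, u: UniversalParams, dCp: float):
    """Per-residue Gibbs energy of unfolding, J/(mol residue).

    Concave in ``T`` with a unique maximum at ``T_S exp(-dS*/dCp)``;
    negative dG means the unfolded state is favoured.
    """
    T = _check_temperature(T)
    if dCp < 0:
        raise ValueError("dCp must be non-negative")
    # dCp = 0 degenerates gracefully to the line dH* - T dS*
    dG = u.dH_star + dCp * (T - u.T_H) - T * (u.dS_star + dCp * np.log(T / u.T_S))
    return dG if dG.ndim else float(dG)


def native_state_probability(T, u: UniversalParams, dCp: float, n: float):
    """Equilibrium probability that the enzyme is in its native state.

    Two-state folding: ``P = 1 / (1 + exp(-n dG / (R T)))``.  Saturates to
    0 or 1 for large ``|n dG / (R T)|`` instead of overflowing.
    """
    T = _check_temperature(T)
    dG = unfolding_free_energy(T, u, dCp)
    # expit-style stable logistic
    x = n * np.asarray(dG) / (R * T)
    with np.errstate(over="ignore", invalid="ignore"):
        P = np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)), np.exp(x) / (1.0 + np.exp(x)))
    return P if P.ndim else float(P)


def log_growth_rate(T, u: UniversalParams, s: StrainParams):
    """Natural log of the modelled growth rate; stable over the full range.

    ``log r = log c + log T - dH_act/(R T) - log(1 + exp(-n dG/(R T)))``,
    the last term computed via log-sum-exp.
    """
    T = _check_temperature(T)
    dG = np.asarray(unfolding_free_energy(T, u, s.dCp))
    x = -s.n * dG / (R * T)
    log_denom = np.logaddexp(0.0, x)
    out = np.log(s.c) + np.log(T) - s.dH_act / (R * T) - log_denom
    return out if out.ndim else float(out)


def growth_rate(T, u: UniversalParams, s: StrainParams):
    """Modelled growth rate at temperature ``T`` (same units as the data).

    Always finite and non-negative: the numerator is an Arrhenius term in
    ``T`` and the denominator is ``1/P_native >= 1``.
    """
    r = np.exp(log_growth_rate(T, u, s))
    return r if np.ndim(r) else float(r)
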