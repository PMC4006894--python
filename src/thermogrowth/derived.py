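"""Derived thermodynamic summaries of a fitted growth curve.

From the universal unfolding parameters and a strain's (or group's)
enzyme parameters the model implies a set of characteristic temperatures:

* ``T_star`` — temperature of maximal unfolding free energy, i.e. where
  denaturation is minimised; closed form ``T_S exp(-dS*/dCp)``.
* ``T_opt`` — temperature of maximal growth rate.
* ``T_L``, ``T_U`` — the two roots of ``dG(T) = 0``, where the enzyme is
  50% denatured, bracketing ``T_star`` (cold and heat denaturation).

plus the protein-chemistry indices ``Nh`` (average non-polar hydrogen
atoms per residue, an increasing function of the per-residue heat-capacity
change) and the total heat-capacity change ``n * dCp``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from . import constants
from .model import StrainParams, UniversalParams, log_growth_rate, unfolding_free_energy

__all__ = [
    "DerivedSummary",
    "stability_temperature",
    "optimal_temperature",
    "half_denaturation_bounds",
    "nonpolar_hydrogens",
    "summarize_group",
    "derived_table",
    "native_state_curve_table",
]

# search bracket for temperature optimisation, K
_T_LO, _T_HI = 200.0, 450.0


@dataclass(frozen=True)
class DerivedSummary:
    """Per-strain or per-group derived temperatures and indices.

    ``d_UO = T_U - T_opt``, ``d_OL = T_opt - T_L``, ``d_OS = T_opt - T_star``
    (all K).  ``total_dCp = n * dCp`` in J/(K·mol).  ``T_L``/``T_U`` are NaN
    when the free energy never reaches zero (enzyme always >= 50% denatured).
    """

    group: str
    Nh: float
    T_star: float
    T_opt: float
    T_L: float
    T_U: float
    d_UO: float
    d_OL: float
    d_OS: float
    total_dCp: float
    flags: str = ""


def stability_temperature(u: UniversalParams, dCp: float) -> float:
    """Temperature (K) at which the unfolding free energy is maximal.

    Stationarity of ``dG`` gives the closed form ``T_S exp(-dS*/dCp)``;
    concavity of ``dG`` makes this the unique maximiser.
    """
    if not dCp > 0:
        raise ValueError("dCp must be strictly positive")
    return u.T_S * float(np.exp(-u.dS_star / dCp))


def optimal_temperature(u: UniversalParams, s: StrainParams,
                        xtol: float = 1e-3) -> tuple[float, bool]:
    """Temperature (K) of maximal growth rate and a unimodality flag.

    A coarse 1 K scan brackets the maximum, which is then refined by
    bounded scalar minimisation of ``-log r`` (invariant to ``c``).
    Returns ``(T_opt, unimodal)``; ``unimodal`` is False when the coarse
    scan sees more than one local maximum (flat-topped hyperthermophile
    curves can do this within numerical noise).
    """
    grid = np.arange(_T_LO, _T_HI + 1.0, 1.0)
    lr = log_growth_rate(grid, u, s)
    i = int(np.argmax(lr))
    interior = lr[1:-1]
    peaks = np.flatnonzero((interior > lr[:-2] + 1e-12) & (interior > lr[2:] + 1e-12))
    unimodal = len(peaks) <= 1
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(lambda T: -log_growth_rate(T, u, s),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": xtol * 0.1})
    return float(res.x), unimodal


def half_denaturation_bounds(u: UniversalParams, dCp: float, n: float | None = None
                             ) -> tuple[float, float]:
    """The two temperatures (K) at which the enzyme is 50% denatured.

    These are the roots of ``dG(T) = 0``; by concavity there is at most one
    on each side of ``T_star``, found by Brent's method.  The roots do not
    depend on ``n`` (``n * 0 = 0``).  Returns ``(nan, nan)`` when
    ``max dG <= 0`` — the enzyme is then always at least half denatured.
    """
    t_star = stability_temperature(u, dCp)
    g = lambda T: unfolding_free_energy(T, u, dCp)
    if g(t_star) <= 0:
        return (float("nan"), float("nan"))
    lo = brentq(g, _T_LO, t_star, xtol=1e-9) if g(_T_LO) < 0 else _T_LO
    hi = brentq(g, t_star, _T_HI, xtol=1e-9) if g(_T_HI) < 0 else _T_HI
    return (float(lo), float(hi))


def nonpolar_hydrogens(dCp: float, n: float,
                       coefficients: tuple[float, float] | None = None) -> float:
    """Average number of non-polar hydrogen atoms per amino-acid residue.

    Computed from the per-residue heat-capacity change through a linear
    hydration relationship ``Nh = slope * dCp + intercept``; the larger the
    apolar surface buried in the fold, the larger the heat-capacity change
    on unfolding.  Coefficients default to the calibrated package values.
    """
    if not (dCp > 0 and n > 0):
        raise ValueError("dCp and n must be strictly positive")
    slope, intercept = coefficients if coefficients is not None else constants.NH_COEFFICIENTS
    if not (20.0 <= dCp <= 120.0):
        warnings.warn(
            f"dCp = {dCp} J/(K mol-residue) is outside the hydration "
            "relationship's calibrated range (20-120)", stacklevel=2)
    return slope * dCp + intercept


def summarize_group(u: UniversalParams, s: StrainParams) -> DerivedSummary:
    """Assemble every derived quantity for one parameter set."""
    t_star = stability_temperature(u, s.dCp)
    t_opt, unimodal = optimal_temperature(u, s)
    t_l, t_u = half_denaturation_bounds(u, s.dCp)
    flags = []
    if not unimodal:
        flags.append("non-unimodal")
    if np.isnan(t_l):
        flags.append("always >=50% denatured")
    return DerivedSummary(
        group=s.group,
        Nh=nonpolar_hydrogens(s.dCp, s.n),
        T_star=t_star,
        T_opt=t_opt,
        T_L=t_l,
        T_U=t_u,
        d_UO=t_u - t_opt,
        d_OL=t_opt - t_l,
        d_OS=t_opt - t_star,
        total_dCp=s.n * s.dCp,
        flags=";".join(flags),
    )


def derived_table(u: UniversalParams,
                  group_params: Mapping[str, StrainParams] | Iterable[StrainParams],
                  ) -> pd.DataFrame:
    """Derived-quantity table (one row per group/strain parameter set)."""
    if isinstance(group_params, Mapping):
        from dataclasses import replace
        items = [sp if sp.group else replace(sp, group=name)
                 for name, sp in group_params.items()]
    else:
        items = list(group_params)
    rows = [asdict(summarize_group(u, s)) for s in items]
    return pd.DataFrame(rows)


def native_state_curve_table(u: UniversalParams,
                             group_params: Mapping[str, StrainParams],
                             T_grid=None) -> pd.DataFrame:
    """Native-state probability on a temperature grid, one column per group."""
    from .model import native_state_probability

    if T_grid is None:
        T_grid = np.arange(260.0, 400.0 + 0.5, 0.5)
    out = {"temperature_K": np.asarray(T_grid, float)}
    for name, s in group_params.items():
        out[name] = native_state_probability(T_grid, u, s.dCp, s.n)
    return pd.DataFrame(out)
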