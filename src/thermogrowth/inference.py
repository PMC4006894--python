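"""Hierarchical Bayesian fitting of the thermodynamic growth model.

Observation model: for every record the square root of the standardised
rate is Gaussian around the square root of the modelled rate with a common
precision ``tau_obs`` (the square-root scale stabilises the variance of
growth-rate measurements).  Strain-level enzyme parameters are Gaussian
around their group means with per-parameter-type precisions; group means,
universal unfolding parameters and the precisions carry the priors in
:class:`~thermogrowth.priors.PriorSpec`.

One MCMC sweep updates, in order: every strain's four-parameter block
(adaptive Metropolis), every group-mean block, the between-strain
log-precision block, the observational precision (conjugate gamma Gibbs
draw — the gamma prior is conjugate on the square-root scale), and finally
the universal parameters by one adaptive-direction ensemble update.

Every block draws from its own seeded random stream keyed by the strain or
group label, so relabelling or permuting strains changes nothing but
labels.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from math import lgamma
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import gamma as gamma_dist

from .constants import R
from .model import StrainParams, UniversalParams, growth_rate, log_growth_rate
from .priors import HIER_PARAMS, PriorSpec
from .samplers import AdaptiveDirectionSampler, HaarioBlock, hpdi
from .structures import ModelStructure

__all__ = [
    "log_likelihood",
    "log_prior",
    "run_mcmc",
    "two_stage_fit",
    "fit_single_strain",
    "GrowthSampler",
    "PosteriorResult",
    "SingleStrainFit",
    "TwoStageError",
]

_LN2PI = float(np.log(2.0 * np.pi))

U_NAMES = ("dH_star", "dS_star", "T_H", "T_S")
STRAIN_PARAM_COLS = ("log_c", "dH_act", "dCp", "n")


def _stream(seed: int, *keys) -> np.random.Generator:
    """Deterministic per-block random stream keyed by strings/ints."""
    words = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        words.append(zlib.crc32(str(k).encode()) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(words))


def _log_normal(x, mean, tau):
    return 0.5 * (np.log(tau) - _LN2PI) - 0.5 * tau * (x - mean) ** 2


# ---------------------------------------------------------------------------
# functional likelihood / prior (also the oracle surface for the engine)
# ---------------------------------------------------------------------------

def log_likelihood(records: pd.DataFrame, u: UniversalParams,
                   strain_params: Mapping[str, StrainParams],
                   tau_obs: float) -> float:
    """Gaussian log-likelihood of sqrt(standardised rate) given the model.

    Sum over records of ``N(sqrt(rate_std) | sqrt(r_model(T)), 1/tau_obs)``.
    """
    if not tau_obs > 0:
        raise ValueError("tau_obs must be positive")
    total = 0.0
    for sid, grp in records.groupby("strain_id", sort=False):
        s = strain_params[sid]
        mu = np.exp(0.5 * log_growth_rate(grp["temperature_K"].to_numpy(), u, s))
        y = np.sqrt(grp["rate_std"].to_numpy())
        total += float(np.sum(_log_normal(y, mu, tau_obs)))
    if not np.isfinite(total):
        raise FloatingPointError("non-finite log-likelihood")
    return total


def log_prior(u: UniversalParams,
              group_means: Mapping[str, Mapping[str, float]],
              strain_params: Mapping[str, StrainParams],
              tau_theta: Mapping[str, float],
              tau_obs: float,
              prior: PriorSpec,
              structure: ModelStructure) -> float:
    """Joint log-prior density of all parameters (fully normalised)."""
    total = prior.log_uniform_universal(u.as_array())
    for g in structure.groups:
        m = group_means[g]
        total += prior.log_uniform_group(np.array([m[p] for p in HIER_PARAMS]))
    tau_vec = np.array([tau_theta[p] for p in HIER_PARAMS])
    total += prior.log_tau_theta_prior(tau_vec)
    log_c = np.array([np.log(strain_params[sid].c) for sid in structure.assignment])
    total += prior.log_uniform_log_c(log_c)
    if not np.isfinite(total):
        return -np.inf
    for sid, gname in structure.assignment.items():
        s = strain_params[sid]
        m = group_means[gname]
        for p in HIER_PARAMS:
            val = getattr(s, "dH_act" if p == "dH_act" else p)
            if val <= 0:
                return -np.inf
            total += float(_log_normal(val, m[p], tau_theta[p]))
    a, b = prior.gamma_obs
    total += float(gamma_dist.logpdf(tau_obs, a, scale=1.0 / b))
    return float(total)


# ---------------------------------------------------------------------------
# the MCMC engine
# ---------------------------------------------------------------------------

class GrowthSampler:
    """Markov-chain engine for one grouping structure.

    ``beta`` tempers the likelihood (``beta = 0`` samples the prior;
    intermediate values are used by the stepping-stone marginal-likelihood
    estimator).  The flat state vector used by ``state``/``set_state``/
    ``log_target`` stacks, in order: the 4 universal parameters, the S×4
    strain parameters (log c, dH_act, dCp, n), the G×3 group means,
    the 3 between-strain log-precisions and log tau_obs; ``log_target``
    is the density the chain targets in those (partly log) coordinates,
    Jacobians included.
    """

    def __init__(self, records: pd.DataFrame, structure: ModelStructure,
                 prior: PriorSpec | None = None, seed: int = 0,
                 beta: float = 1.0, ads_members: int = 5,
                 stepping_stone_prob: float = 0.05,
                 haario_warmup: int = 1000):
        self.prior = prior or PriorSpec()
        self.structure = structure
        self.beta = float(beta)
        self.seed = int(seed)

        if "rate_std" not in records.columns:
            raise ValueError("records must carry a rate_std column "
                             "(standardise first)")
        recs = records.sort_values(["strain_id", "temperature_K"],
                                   kind="mergesort").reset_index(drop=True)
        self.strain_ids = sorted(recs["strain_id"].unique())
        missing = set(self.strain_ids) - set(structure.assignment)
        if missing:
            raise ValueError(f"structure lacks assignments for strains: {missing}")
        self.S = len(self.strain_ids)
        self.groups = list(structure.groups)
        self.G = len(self.groups)
        sid_to_idx = {s: i for i, s in enumerate(self.strain_ids)}
        self.g_of_s = np.array([self.groups.index(structure.assignment[s])
                                for s in self.strain_ids])
        self.members_of_g = [np.flatnonzero(self.g_of_s == g) for g in range(self.G)]

        self.T_all = recs["temperature_K"].to_numpy(float)
        self.y_all = np.sqrt(recs["rate_std"].to_numpy(float))
        self.rec_strain = recs["strain_id"].map(sid_to_idx).to_numpy()
        order = np.argsort(self.rec_strain, kind="stable")
        self.T_all, self.y_all = self.T_all[order], self.y_all[order]
        self.rec_strain = self.rec_strain[order]
        self.N = len(self.T_all)
        self.N_s = np.bincount(self.rec_strain, minlength=self.S)
        bounds = np.concatenate([[0], np.cumsum(self.N_s)])
        self.slices = [slice(bounds[i], bounds[i + 1]) for i in range(self.S)]
        self._logT = np.log(self.T_all)
        self._invRT = 1.0 / (R * self.T_all)

        # --- initial state -------------------------------------------------
        self.u = self.prior.universal_midpoint()
        # geometric midpoints keep the precisions inside their prior boxes
        self.log_tau = np.array([
            0.5 * (np.log(lo) + np.log(hi))
            for lo, hi in (self.prior.tau_theta_bounds[p] for p in HIER_PARAMS)])
        self.tau_obs = 1.0
        self._recs_by_strain = {
            sid: recs[recs["strain_id"] == sid] for sid in self.strain_ids}
        self.P = np.zeros((self.S, 4))
        for i in range(self.S):
            self.P[i] = self._init_strain(i)
        # joint least-squares polish over the universal and all strain
        # parameters: the hot-side fit is so sharp that per-strain
        # estimates at a slightly wrong T_S land in a spurious low-n basin
        # that coordinate-wise refits cannot escape
        self.u, self.P = self._joint_ls()
        # group means start at the average of their members' starting values
        self.M = np.empty((self.G, 3))
        for g in range(self.G):
            m = self.P[self.members_of_g[g], 1:].mean(axis=0)
            for j, p in enumerate(HIER_PARAMS):
                lo, hi = self.prior.group_bounds[p]
                self.M[g, j] = float(np.clip(m[j], lo, hi))
        self.ssr = self._all_ssr(self.u)
        if not np.all(np.isfinite(self.ssr)):
            # fall back to prior midpoints
            self.M = np.tile(self.prior.group_midpoint(), (self.G, 1))
            for i in range(self.S):
                self.P[i, 1:] = self.M[self.g_of_s[i]]
                self.P[i, 0] = self._match_log_c(i)
            self.ssr = self._all_ssr(self.u)
            if not np.all(np.isfinite(self.ssr)):
                raise RuntimeError("non-finite residuals at initialisation; "
                                   "check the input records")

        # --- samplers ------------------------------------------------------
        self._strain_rng = [_stream(seed, "strain", s) for s in self.strain_ids]
        self._group_rng = [_stream(seed, "group", g) for g in self.groups]
        self._tau_rng = _stream(seed, "tau_theta")
        self._obs_rng = _stream(seed, "tau_obs")
        self._ads_rng = _stream(seed, "universal")

        self._strain_blocks = [
            HaarioBlock([0.05,
                         max(0.01 * self.P[i, 1], 100.0),
                         max(0.01 * self.P[i, 2], 0.2),
                         max(0.01 * self.P[i, 3], 2.0)],
                        warmup=haario_warmup)
            for i in range(self.S)]
        self._group_blocks = [
            HaarioBlock([1000.0, 1.0, 10.0], warmup=haario_warmup)
            for _ in range(self.G)]
        self._shift_blocks = [
            HaarioBlock([1000.0, 1.0, 10.0], warmup=haario_warmup)
            for _ in range(self.G)]
        self._shift_rng = [_stream(seed, "shift", g) for g in self.groups]
        self._ridge_rng = _stream(seed, "ridge")
        self._comp_rng = _stream(seed, "compensated")
        # per-coordinate proposal scales for the compensated universal
        # moves, Robbins-Monro adapted toward ~30% acceptance
        self._comp_log_scale = np.zeros(4)
        self._comp_base_scale = np.array([30.0, 0.1, 0.3, 0.3])
        self._comp_count = 0
        self._comp_accepts = np.zeros(4)
        grams = []
        for i in range(self.S):
            a = self._invRT[self.slices[i]]
            g = np.array([[len(a), -np.sum(a)], [-np.sum(a), np.dot(a, a)]])
            grams.append(np.linalg.inv(g))
        self._shear_gram_inv = np.array(grams)
        self._tau_block = HaarioBlock([0.2, 0.2, 0.2], warmup=haario_warmup)

        widths = np.array([hi - lo for lo, hi in
                           (self.prior.universal_bounds[k] for k in U_NAMES)])
        init_rng = _stream(seed, "ads_init")
        pts = self.u + 0.005 * widths * init_rng.standard_normal((ads_members, 4))
        pts[0] = self.u
        self._ads = AdaptiveDirectionSampler(
            pts, stepping_stone_prob=stepping_stone_prob,
            stone_sampler=self._stone_sample, stone_logpdf=self._stone_logpdf)
        self.iteration = 0

    # -- model evaluation ---------------------------------------------------

    def _ssr_on(self, sl: slice, u_vec, lc, dH, dCp, n) -> float:
        T = self.T_all[sl]
        dG = (u_vec[0] + dCp * (T - u_vec[2])
              - T * (u_vec[1] + dCp * (self._logT[sl] - np.log(u_vec[3]))))
        x = -n * dG * self._invRT[sl]
        logr = lc + self._logT[sl] - dH * self._invRT[sl] - np.logaddexp(0.0, x)
        with np.errstate(over="ignore"):
            res = self.y_all[sl] - np.exp(0.5 * logr)
        return float(res @ res)

    def _all_ssr(self, u_vec, P=None) -> np.ndarray:
        P = self.P if P is None else P
        lc = P[self.rec_strain, 0]
        dH = P[self.rec_strain, 1]
        dCp = P[self.rec_strain, 2]
        n = P[self.rec_strain, 3]
        T = self.T_all
        dG = (u_vec[0] + dCp * (T - u_vec[2])
              - T * (u_vec[1] + dCp * (self._logT - np.log(u_vec[3]))))
        x = -n * dG * self._invRT
        logr = lc + self._logT - dH * self._invRT - np.logaddexp(0.0, x)
        with np.errstate(over="ignore"):
            res = self.y_all - np.exp(0.5 * logr)
        return np.bincount(self.rec_strain, weights=res * res, minlength=self.S)

    def _joint_ls(self) -> tuple[np.ndarray, np.ndarray]:
        """Joint least-squares refinement of the universal and every
        strain's parameters, bounded by the prior boxes."""
        ub = self.prior.universal_bounds
        gb = self.prior.group_bounds
        lcb = self.prior.log_c_bounds
        lo = [ub[k][0] for k in U_NAMES]
        hi = [ub[k][1] for k in U_NAMES]
        lo += [lcb[0], gb["dH_act"][0], gb["dCp"][0], gb["n"][0]] * self.S
        hi += [lcb[1], gb["dH_act"][1], gb["dCp"][1], gb["n"][1]] * self.S
        lo, hi = np.array(lo), np.array(hi)

        def residuals(theta):
            u = theta[:4]
            P = theta[4:].reshape(self.S, 4)
            lc = P[self.rec_strain, 0]
            dH = P[self.rec_strain, 1]
            dCp = P[self.rec_strain, 2]
            n = P[self.rec_strain, 3]
            T = self.T_all
            dG = (u[0] + dCp * (T - u[2])
                  - T * (u[1] + dCp * (self._logT - np.log(u[3]))))
            logr = (lc + self._logT - dH * self._invRT
                    - np.logaddexp(0.0, -n * dG * self._invRT))
            with np.errstate(over="ignore"):
                mu = np.exp(0.5 * logr)
            return np.where(np.isfinite(mu), self.y_all - mu, 1e6)

        theta0 = np.clip(np.concatenate([self.u, self.P.ravel()]),
                         lo + 1e-9, hi - 1e-9)
        try:
            res = least_squares(residuals, theta0, bounds=(lo, hi),
                                x_scale="jac", method="trf", max_nfev=500)
            theta = res.x
        except Exception:
            theta = theta0
        u = theta[:4].copy()
        if not u[2] < u[3]:
            u = self.u
        return u, theta[4:].reshape(self.S, 4).copy()

    def _init_strain(self, i: int, refine_only: bool = False) -> np.ndarray:
        """Deterministic start for one strain: least squares on its own
        records with the universal parameters held fixed, clipped into the
        prior's support.  Falls back to group-box midpoints on failure."""
        sid = self.strain_ids[i]
        fixed = {"dH_star": self.u[0], "dS_star": self.u[1],
                 "T_H": self.u[2], "T_S": self.u[3]}
        try:
            # the per-strain likelihood is ridged in n: refine from several
            # residue-count starts and keep the best least-squares fit
            best = None
            starts = [{"n": n0} for n0 in (100.0, 250.0, 450.0, 700.0)]
            if refine_only:
                # keep the current estimate in the running as a warm start
                starts.append({"c": float(np.exp(self.P[i, 0])),
                               "dH_act": self.P[i, 1], "dCp": self.P[i, 2],
                               "n": self.P[i, 3]})
            for init in starts:
                try:
                    fit = fit_single_strain(self._recs_by_strain[sid],
                                            fixed=fixed, init=init)
                except Exception:
                    continue
                if best is None or fit.cost < best.cost:
                    best = fit
            if best is None:
                raise RuntimeError("initial least-squares fits failed")
            p = best.params
            vec = np.array([np.log(p["c"]), p["dH_act"], p["dCp"], p["n"]])
        except Exception:
            self.P[i, 1:] = self.prior.group_midpoint()
            self.P[i, 0] = 0.0
            self.P[i, 0] = self._match_log_c(i)
            return self.P[i].copy()
        for j, name in enumerate(HIER_PARAMS):
            lo, hi = self.prior.group_bounds[name]
            vec[j + 1] = float(np.clip(vec[j + 1], lo, hi))
        lo, hi = self.prior.log_c_bounds
        vec[0] = float(np.clip(vec[0], lo, hi))
        return vec

    def _log_denom(self, sl: slice, u_vec, dCp: float, n: float) -> np.ndarray:
        """log(1 + exp(-n dG / RT)) on one strain's records."""
        T = self.T_all[sl]
        dG = (u_vec[0] + dCp * (T - u_vec[2])
              - T * (u_vec[1] + dCp * (self._logT[sl] - np.log(u_vec[3]))))
        return np.logaddexp(0.0, -n * dG * self._invRT[sl])

    def _log_denom_all(self, u_vec, P) -> np.ndarray:
        """log(1 + exp(-n dG / RT)) for every record at once."""
        dCp = P[self.rec_strain, 2]
        n = P[self.rec_strain, 3]
        T = self.T_all
        dG = (u_vec[0] + dCp * (T - u_vec[2])
              - T * (u_vec[1] + dCp * (self._logT - np.log(u_vec[3]))))
        return np.logaddexp(0.0, -n * dG * self._invRT)

    def _match_log_c(self, i: int) -> float:
        """Deterministic log-c start: modelled rate equals the observed
        maximum at the temperature where it was observed."""
        sl = self.slices[i]
        j = int(np.argmax(self.y_all[sl]))
        T_pk = self.T_all[sl][j]
        y_pk = self.y_all[sl][j]
        s = StrainParams(c=1.0, dH_act=self.P[i, 1], dCp=self.P[i, 2],
                         n=self.P[i, 3])
        u = UniversalParams.from_array(self.u)
        lc = 2.0 * np.log(max(y_pk, 1e-6)) - log_growth_rate(float(T_pk), u, s)
        lo, hi = self.prior.log_c_bounds
        return float(np.clip(lc, lo, hi))

    # -- log-density pieces -------------------------------------------------

    def _strain_prior(self, p_vec, g: int) -> float:
        if p_vec[1] <= 0 or p_vec[2] <= 0 or p_vec[3] <= 0:
            return -np.inf
        lo, hi = self.prior.log_c_bounds
        if not lo <= p_vec[0] <= hi:
            return -np.inf
        tau = np.exp(self.log_tau)
        return float(np.sum(_log_normal(p_vec[1:], self.M[g], tau))) - np.log(hi - lo)

    def _strain_logpost(self, i: int, p_vec, out_ssr: list) -> float:
        lp = self._strain_prior(p_vec, self.g_of_s[i])
        if not np.isfinite(lp):
            return -np.inf
        ssr = self._ssr_on(self.slices[i], self.u, *p_vec)
        out_ssr[0] = ssr
        if not np.isfinite(ssr):
            return -np.inf
        return lp - 0.5 * self.beta * self.tau_obs * ssr

    def _group_logpost(self, g: int, m_vec) -> float:
        lp = self.prior.log_uniform_group(m_vec)
        if not np.isfinite(lp):
            return -np.inf
        tau = np.exp(self.log_tau)
        mem = self.members_of_g[g]
        return lp + float(np.sum(_log_normal(self.P[mem, 1:], m_vec, tau)))

    def _shift_logpost(self, g: int, m_vec, out_ssr: list) -> float:
        """Density for translating a group mean together with all member
        strains (the between-strain Gaussian terms are invariant)."""
        lp = self.prior.log_uniform_group(m_vec)
        if not np.isfinite(lp):
            return -np.inf
        delta = np.asarray(m_vec) - self.M[g]
        mem = self.members_of_g[g]
        ssr_new = np.empty(len(mem))
        for j, i in enumerate(mem):
            p = self.P[i, 1:] + delta
            if np.any(p <= 0):
                return -np.inf
            ssr_new[j] = self._ssr_on(self.slices[i], self.u,
                                      self.P[i, 0], *p)
        if not np.all(np.isfinite(ssr_new)):
            return -np.inf
        out_ssr[0] = ssr_new
        return lp - 0.5 * self.beta * self.tau_obs * float(np.sum(ssr_new))

    def _ridge_move(self) -> None:
        """Metropolis move along the exact scale-invariance ridge:
        (dH*, dS*, every dCp) times lambda, every n divided by lambda.
        The likelihood is invariant, so only the prior and the Jacobian
        (lambda squared) enter the acceptance ratio."""
        eps = 0.02 * self._ridge_rng.standard_normal()
        lam = float(np.exp(eps))
        lp0 = self._log_prior_state()
        saved = (self.u.copy(), self.P.copy(), self.M.copy())
        self.u[0] *= lam
        self.u[1] *= lam
        self.P[:, 2] *= lam
        self.P[:, 3] /= lam
        self.M[:, 1] *= lam
        self.M[:, 2] /= lam
        lp1 = self._log_prior_state()
        if np.log(self._ridge_rng.random()) < lp1 - lp0 + 2.0 * eps:
            self._ads.points[0] = self.u
            self._ads.invalidate()
        else:
            self.u, self.P, self.M = saved

    def _compensated_u_move(self, coord: int) -> None:
        """Metropolis move of one universal coordinate with deterministic
        compensation of every strain's (dCp, n).

        The likelihood depends on ``(u, dCp_i, n_i)`` only through the
        per-strain combinations ``x_i = n_i dCp_i``,
        ``a_i = n_i dH* - x_i T_H`` and
        ``b_i = x_i (1 + ln T_S) - n_i dS*``.  Conditional updates of ``u``
        alone are frozen by the razor-thin conditional; here the proposal
        shifts one universal coordinate and rescales each ``(dCp_i, n_i)``
        (and the group means) to keep ``x_i`` and the matching combination
        exactly invariant, leaving only a soft likelihood change.  The
        transformation is an exact involution under sign flip of the step,
        so the Hastings factor is its Jacobian.
        """
        scale = self._comp_base_scale[coord] * np.exp(self._comp_log_scale[coord])
        delta = float(scale * self._comp_rng.standard_normal())
        u = self.u
        dH_star, dS_star, T_H, T_S = u
        if coord == 0:      # dH* shift: preserves a_i; det = 1 per strain
            factor_of = lambda dCp: np.full_like(dCp, dH_star / (dH_star + delta))
            new_u = np.array([dH_star + delta, dS_star, T_H, T_S])
        elif coord == 1:    # dS* shift: preserves b_i; det = 1 per strain
            factor_of = lambda dCp: np.full_like(dCp, dS_star / (dS_star + delta))
            new_u = np.array([dH_star, dS_star + delta, T_H, T_S])
        elif coord == 2:    # T_H shift: preserves a_i; det = prod 1/f
            kappa = delta / dH_star
            factor_of = lambda dCp: 1.0 + dCp * kappa
            new_u = np.array([dH_star, dS_star, T_H + delta, T_S])
        else:               # T_S shift: preserves b_i; det = prod 1/f
            kappa = float(np.log((T_S + delta) / T_S)) / dS_star
            factor_of = lambda dCp: 1.0 + dCp * kappa
            new_u = np.array([dH_star, dS_star, T_H, T_S + delta])

        f_strain = factor_of(self.P[:, 2])
        f_group = factor_of(self.M[:, 1])
        accepted = False
        if (np.all(f_strain > 0.05) and np.all(f_group > 0.05)
                and np.isfinite(self.prior.log_uniform_universal(new_u))):
            lp0 = self._log_prior_state() + self.beta * self.loglik()
            saved = (self.u, self.P, self.M, self.ssr)
            P = self.P.copy()
            M = self.M.copy()
            P[:, 3] = self.P[:, 3] * f_strain
            P[:, 2] = self.P[:, 2] / f_strain
            M[:, 2] = self.M[:, 2] * f_group
            M[:, 1] = self.M[:, 1] / f_group
            # absorb the leftover free-energy shift into (log c, dH_act):
            # a per-strain linear projection of the log-rate change onto
            # (1, -1/RT); independent of (log c, dH_act) themselves, hence
            # a unit-Jacobian shear
            d = (self._log_denom_all(self.u, self.P)
                 - self._log_denom_all(new_u, P))
            # per-strain 2x2 normal equations for regressors (1, -1/RT)
            rhs1 = -np.bincount(self.rec_strain, weights=d, minlength=self.S)
            rhs2 = np.bincount(self.rec_strain, weights=self._invRT * d,
                               minlength=self.S)
            gi = self._shear_gram_inv
            lc_shift = gi[:, 0, 0] * rhs1 + gi[:, 0, 1] * rhs2
            dH_shift = gi[:, 1, 0] * rhs1 + gi[:, 1, 1] * rhs2
            P[:, 0] += lc_shift
            P[:, 1] += dH_shift
            for g in range(self.G):
                M[g, 0] += float(np.mean(dH_shift[self.members_of_g[g]]))
            if np.any(P[:, 1] <= 0) or np.any(M[:, 0] <= 0):
                lp1 = -np.inf
            else:
                self.u, self.P, self.M = new_u, P, M
                self.ssr = self._all_ssr(new_u)
                lp1 = self._log_prior_state() + self.beta * self.loglik()
            # Jacobians: coords 0/1 are volume-preserving shears; 2/3
            # contribute 1/f per strain and per group mean
            log_jac = 0.0
            if coord >= 2:
                log_jac = -float(np.sum(np.log(f_strain))
                                 + np.sum(np.log(f_group)))
            if (np.isfinite(lp1)
                    and np.log(self._comp_rng.random()) < lp1 - lp0 + log_jac):
                accepted = True
                self._comp_accepts[coord] += 1
                self._ads.points[0] = self.u
                self._ads.invalidate()
            else:
                self.u, self.P, self.M, self.ssr = saved
        # Robbins-Monro step-size adaptation
        self._comp_count += 1
        step = 2.0 / max(self._comp_count, 20) ** 0.6
        self._comp_log_scale[coord] += step * ((1.0 if accepted else 0.0) - 0.3)
        self._comp_log_scale[coord] = float(
            np.clip(self._comp_log_scale[coord], -8.0, 8.0))

    def _tau_logpost(self, log_tau_vec) -> float:
        tau = np.exp(log_tau_vec)
        lp = self.prior.log_tau_theta_prior(tau)
        if not np.isfinite(lp):
            return -np.inf
        lp += float(np.sum(log_tau_vec))  # Jacobian of the log transform
        dev = self.P[:, 1:] - self.M[self.g_of_s]
        lp += float(np.sum(_log_normal(dev, 0.0, tau)))
        return lp

    def _u_logpost(self, u_vec) -> float:
        lp = self.prior.log_uniform_universal(u_vec)
        if not np.isfinite(lp):
            return -np.inf
        ssr = self._all_ssr(u_vec)
        total = float(np.sum(ssr))
        if not np.isfinite(total):
            return -np.inf
        return lp - 0.5 * self.beta * self.tau_obs * total

    def _stone_sample(self, rng) -> np.ndarray:
        for _ in range(100):
            v = np.array([rng.uniform(*self.prior.universal_bounds[k])
                          for k in U_NAMES])
            if v[2] < v[3]:
                return v
        return self.u.copy()

    def _stone_logpdf(self, v) -> float:
        return self.prior.log_uniform_universal(np.asarray(v))

    # -- full densities -----------------------------------------------------

    def loglik(self) -> float:
        """Untempered log-likelihood at the current state."""
        total = float(np.sum(self.ssr))
        return 0.5 * self.N * (np.log(self.tau_obs) - _LN2PI) \
            - 0.5 * self.tau_obs * total

    def _log_prior_state(self) -> float:
        lp = self.prior.log_uniform_universal(self.u)
        for g in range(self.G):
            lp += self.prior.log_uniform_group(self.M[g])
        if not np.isfinite(lp):
            return -np.inf
        tau = np.exp(self.log_tau)
        lp += self.prior.log_tau_theta_prior(tau)
        lp += float(np.sum(self.log_tau))  # Jacobian
        lp += self.prior.log_uniform_log_c(self.P[:, 0])
        if not np.isfinite(lp):
            return -np.inf
        if np.any(self.P[:, 1:] <= 0):
            return -np.inf
        dev = self.P[:, 1:] - self.M[self.g_of_s]
        lp += float(np.sum(_log_normal(dev, 0.0, tau)))
        a, b = self.prior.gamma_obs
        lp += (a * np.log(b) - lgamma(a) + (a - 1.0) * np.log(self.tau_obs)
               - b * self.tau_obs)
        lp += float(np.log(self.tau_obs))  # Jacobian for log tau_obs coords
        return lp

    def log_target(self, v: np.ndarray | None = None) -> float:
        """Tempered posterior density in sampling coordinates."""
        if v is not None:
            saved = self.state()
            try:
                self.set_state(v)
                return self.log_target()
            finally:
                self.set_state(saved)
        lp = self._log_prior_state()
        if not np.isfinite(lp):
            return -np.inf
        return lp + self.beta * self.loglik()

    # -- flat-state plumbing ------------------------------------------------

    def state(self) -> np.ndarray:
        return np.concatenate([self.u, self.P.ravel(), self.M.ravel(),
                               self.log_tau, [np.log(self.tau_obs)]])

    def set_state(self, v: np.ndarray) -> None:
        v = np.asarray(v, float)
        k = 0
        self.u = v[k:k + 4].copy(); k += 4
        self.P = v[k:k + 4 * self.S].reshape(self.S, 4).copy(); k += 4 * self.S
        self.M = v[k:k + 3 * self.G].reshape(self.G, 3).copy(); k += 3 * self.G
        self.log_tau = v[k:k + 3].copy(); k += 3
        self.tau_obs = float(np.exp(v[k]))
        with np.errstate(invalid="ignore"):
            self.ssr = self._all_ssr(self.u)
        self._ads.points[0] = self.u
        self._ads.invalidate()

    def set_beta(self, beta: float) -> None:
        self.beta = float(beta)
        self._ads.invalidate()

    def param_names(self) -> list[str]:
        names = list(U_NAMES)
        for sid in self.strain_ids:
            names += [f"{sid}:{p}" for p in STRAIN_PARAM_COLS]
        for g in self.groups:
            names += [f"{g}:{p}" for p in HIER_PARAMS]
        names += [f"tau_theta_{p}" for p in HIER_PARAMS]
        names.append("log_tau_obs")
        return names

    # -- sweeps -------------------------------------------------------------

    def sweep(self) -> None:
        """One full MCMC iteration over all blocks."""
        out = [0.0]
        for i in range(self.S):
            lp0 = self._strain_logpost(i, self.P[i], out)
            new, _, acc = self._strain_blocks[i].step(
                self.P[i], lambda p: self._strain_logpost(i, p, out), lp0,
                self._strain_rng[i])
            if acc:
                self.P[i] = new
                self.ssr[i] = out[0]
        for g in range(self.G):
            lp0 = self._group_logpost(g, self.M[g])
            new, _, acc = self._group_blocks[g].step(
                self.M[g], lambda m: self._group_logpost(g, m), lp0,
                self._group_rng[g])
            if acc:
                self.M[g] = new
        # joint translation of each group mean with its member strains
        out_shift = [None]
        for g in range(self.G):
            lp0 = self._shift_logpost(g, self.M[g], out_shift)
            old = self.M[g].copy()
            new, _, acc = self._shift_blocks[g].step(
                self.M[g], lambda m: self._shift_logpost(g, m, out_shift),
                lp0, self._shift_rng[g])
            if acc:
                delta = new - old
                self.M[g] = new
                mem = self.members_of_g[g]
                self.P[mem, 1:] += delta
                self.ssr[mem] = out_shift[0]
        self._ridge_move()
        for coord in range(4):
            self._compensated_u_move(coord)
        lp0 = self._tau_logpost(self.log_tau)
        new, _, acc = self._tau_block.step(
            self.log_tau, self._tau_logpost, lp0, self._tau_rng)
        if acc:
            self.log_tau = new
        # conjugate Gibbs draw for the observational precision
        a, b = self.prior.gamma_obs
        shape = a + 0.5 * self.beta * self.N
        rate = b + 0.5 * self.beta * float(np.sum(self.ssr))
        # floor guards against underflow to zero for vague shapes (beta ~ 0)
        self.tau_obs = max(float(self._obs_rng.gamma(shape, 1.0 / rate)), 1e-290)
        # adaptive-direction update of the universal parameters
        self._ads.invalidate()
        self._ads.step(self._u_logpost, self._ads_rng)
        if not np.array_equal(self._ads.state, self.u):
            self.u = self._ads.state
            self.ssr = self._all_ssr(self.u)
        self.iteration += 1

    def acceptance_rates(self) -> dict[str, float]:
        rates = {f"strain:{sid}": b.acceptance_rate
                 for sid, b in zip(self.strain_ids, self._strain_blocks)}
        rates.update({f"group:{g}": b.acceptance_rate
                      for g, b in zip(self.groups, self._group_blocks)})
        rates["tau_theta"] = self._tau_block.acceptance_rate
        rates["universal"] = self._ads.acceptance_rate
        if self._comp_count:
            for j, name in enumerate(U_NAMES):
                rates[f"compensated:{name}"] = (
                    4.0 * self._comp_accepts[j] / self._comp_count)
        return rates

    def run(self, iterations: int, record: bool = True,
            log_posterior_trace: bool = True) -> np.ndarray | None:
        """Run ``iterations`` sweeps; returns the chain matrix if recording."""
        if not record:
            for _ in range(iterations):
                self.sweep()
            return None
        d = 4 + 4 * self.S + 3 * self.G + 3 + 1
        chain = np.empty((iterations, d))
        self._logpost_trace = np.empty(iterations) if log_posterior_trace else None
        for t in range(iterations):
            self.sweep()
            chain[t] = self.state()
            if log_posterior_trace:
                self._logpost_trace[t] = self.log_target()
        return chain


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorResult:
    """Chains and posterior summaries of one hierarchical fit.

    ``chains`` maps parameter names to full-length sampled values;
    summaries are computed on the retained (post burn-in) samples only.
    """

    chains: dict
    burn_in: float
    iterations: int
    seed: int
    structure_name: str
    strain_ids: list
    groups: list
    acceptance_rates: dict = field(default_factory=dict)
    log_posterior: np.ndarray | None = None
    hpdi_level: float = 0.99

    def __post_init__(self) -> None:
        if not 0.0 <= self.burn_in < 1.0:
            raise ValueError("burn_in fraction must be in [0, 1)")

    def retained(self, name: str) -> np.ndarray:
        x = self.chains[name]
        return x[int(len(x) * self.burn_in):]

    @property
    def parameter_names(self) -> list[str]:
        return list(self.chains)

    def posterior_mean(self, name: str) -> float:
        return float(np.mean(self.retained(name)))

    def posterior_sd(self, name: str) -> float:
        return float(np.std(self.retained(name), ddof=1))

    def hpdi(self, name: str, level: float | None = None) -> tuple[float, float]:
        return hpdi(self.retained(name), level or self.hpdi_level)

    def diagnostics(self) -> pd.DataFrame:
        """Split-R-hat and effective sample size per parameter (arviz)."""
        import arviz as az

        rows = []
        for name in self.chains:
            x = self.retained(name)
            half = len(x) // 2
            split = np.stack([x[:half], x[half:2 * half]])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rhat = float(az.rhat(split))
                ess = float(az.ess(split))
            rows.append({"parameter": name, "rhat": rhat, "ess": ess})
        return pd.DataFrame(rows).set_index("parameter")

    def summary(self, level: float | None = None) -> pd.DataFrame:
        level = level or self.hpdi_level
        rows = []
        for name in self.chains:
            lo, hi = self.hpdi(name, level)
            rows.append({"parameter": name,
                         "mean": self.posterior_mean(name),
                         "sd": self.posterior_sd(name),
                         f"hpdi_{level:g}_low": lo,
                         f"hpdi_{level:g}_high": hi})
        return pd.DataFrame(rows).set_index("parameter")

    def summary_table(self, names: Sequence[str] | None = None,
                      level: float | None = None, digits: int = 1) -> pd.DataFrame:
        """Report-style table: ``mean (hpdi_low, hpdi_high)`` strings."""
        names = list(names) if names is not None else list(self.chains)
        rows = []
        for name in names:
            m = self.posterior_mean(name)
            lo, hi = self.hpdi(name, level)
            rows.append({"parameter": name,
                         "estimate": f"{m:.{digits}f} ({lo:.{digits}f}, {hi:.{digits}f})"})
        return pd.DataFrame(rows).set_index("parameter")

    def universal_params(self) -> UniversalParams:
        return UniversalParams(*(self.posterior_mean(k) for k in U_NAMES))

    def group_params(self, c: float = 1.0) -> dict:
        out = {}
        for g in self.groups:
            out[g] = StrainParams(
                c=c, dH_act=self.posterior_mean(f"{g}:dH_act"),
                dCp=self.posterior_mean(f"{g}:dCp"),
                n=self.posterior_mean(f"{g}:n"), group=g)
        return out

    def strain_params(self) -> dict:
        out = {}
        for sid in self.strain_ids:
            out[sid] = StrainParams(
                c=float(np.exp(self.posterior_mean(f"{sid}:log_c"))),
                dH_act=self.posterior_mean(f"{sid}:dH_act"),
                dCp=self.posterior_mean(f"{sid}:dCp"),
                n=self.posterior_mean(f"{sid}:n"))
        return out

    def to_files(self, directory) -> None:
        """Write chains as CSV and a JSON summary."""
        import json
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.chains).to_csv(d / "chains.csv", index=False)
        summ = {
            "structure": self.structure_name,
            "iterations": self.iterations,
            "burn_in": self.burn_in,
            "seed": self.seed,
            "acceptance_rates": {k: float(v) for k, v in
                                 self.acceptance_rates.items()},
            "parameters": {
                name: {"mean": self.posterior_mean(name),
                       "sd": self.posterior_sd(name),
                       "hpdi": list(self.hpdi(name))}
                for name in self.chains},
        }
        with open(d / "summary.json", "w") as fh:
            json.dump(summ, fh, indent=1)


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def run_mcmc(records: pd.DataFrame, structure: ModelStructure,
             prior: PriorSpec | None = None, iterations: int = 50_000,
             burn_in: float = 0.5, seed: int = 0, beta: float = 1.0,
             **engine_kwargs) -> PosteriorResult:
    """Fit the hierarchical model by MCMC; deterministic given ``seed``.

    ``beta = 0`` runs the sampler on the prior alone (likelihood off).
    """
    engine = GrowthSampler(records, structure, prior, seed=seed, beta=beta,
                           **engine_kwargs)
    chain = engine.run(iterations, record=True)
    names = engine.param_names()
    chains = {name: chain[:, j].copy() for j, name in enumerate(names)}
    chains["tau_obs"] = np.exp(chains.pop("log_tau_obs"))
    for p in HIER_PARAMS:
        chains[f"tau_theta_{p}"] = np.exp(chains[f"tau_theta_{p}"])
    return PosteriorResult(
        chains=chains, burn_in=burn_in, iterations=iterations, seed=seed,
        structure_name=structure.name, strain_ids=engine.strain_ids,
        groups=engine.groups, acceptance_rates=engine.acceptance_rates(),
        log_posterior=engine._logpost_trace)


class TwoStageError(RuntimeError):
    """Stage-1 fit failed its convergence diagnostics."""


def two_stage_fit(records: pd.DataFrame, structure: ModelStructure,
                  prior: PriorSpec | None = None, iterations: int = 50_000,
                  burn_in: float = 0.5, seed: int = 0,
                  rhat_abort: float = 1.5, **engine_kwargs):
    """Two-stage standardisation fit.

    Stage 1 fits the max-standardised data; each strain's observed rates
    are then divided by its *fitted* maximum rate and the model is refitted
    (stage 2).  After rescaling, the fitted curves have maxima near one, so
    the scaling constant ``c`` carries no remaining information.  Returns
    the stage-2 result with the stage-1 result attached as ``.stage1``.
    """
    stage1 = run_mcmc(records, structure, prior, iterations, burn_in, seed,
                      **engine_kwargs)
    if rhat_abort is not None:
        diag = stage1.diagnostics()
        check = [n for n in stage1.parameter_names
                 if n in U_NAMES
                 or (":" in n and n.split(":")[0] in stage1.groups)]
        worst = diag.loc[check, "rhat"].max()
        if worst > rhat_abort:
            raise TwoStageError(
                f"stage-1 split-R-hat {worst:.3f} exceeds {rhat_abort}; "
                "diagnostics:\n" + diag.loc[check].to_string())
    u = stage1.universal_params()
    fitted = stage1.strain_params()
    from .derived import optimal_temperature

    rescaled = records.copy()
    for sid, s in fitted.items():
        t_opt, _ = optimal_temperature(u, s)
        r_max = growth_rate(t_opt, u, s)
        mask = rescaled["strain_id"] == sid
        rescaled.loc[mask, "rate_std"] = (
            rescaled.loc[mask, "rate_std"] / r_max)
    stage2 = run_mcmc(rescaled, structure, prior, iterations, burn_in,
                      seed + 1, **engine_kwargs)
    stage2.stage1 = stage1
    return stage2


# ---------------------------------------------------------------------------
# single-strain nonlinear least squares
# ---------------------------------------------------------------------------

@dataclass
class SingleStrainFit:
    """Point estimates from a square-root-scale nonlinear least-squares fit."""

    params: dict
    fixed: dict
    success: bool
    cost: float
    nfev: int
    message: str

    def strain_params(self, group: str = "") -> StrainParams:
        p = self.params
        return StrainParams(c=p["c"], dH_act=p["dH_act"], dCp=p["dCp"],
                            n=p["n"], group=group)


_SINGLE_DEFAULTS = {
    "c": None,  # matched to the data peak
    "dH_act": 60e3, "dCp": 60.0, "n": 300.0,
    "dH_star": 4874.0, "dS_star": 17.0, "T_H": 375.5, "T_S": 390.9,
}
_ALL_PARAMS = tuple(_SINGLE_DEFAULTS)


def fit_single_strain(records: pd.DataFrame,
                      fixed: Mapping[str, float] | None = None,
                      init: Mapping[str, float] | None = None,
                      rate_col: str = "rate_std") -> SingleStrainFit:
    """Least-squares fit of one strain's growth curve on the sqrt scale.

    ``fixed`` maps parameter names to frozen values; the classical scheme
    freezes the two convergence temperatures and ``dS_star`` and estimates
    ``c, dH_act, dCp, dH_star, n``.  ``c`` is optimised on the log scale.
    """
    if fixed is None:
        fixed = {"dS_star": 17.0, "T_H": 375.5, "T_S": 390.9}
    T = records["temperature_K"].to_numpy(float)
    y = np.sqrt(records[rate_col].to_numpy(float))
    if len(T) < len([p for p in _ALL_PARAMS if p not in fixed]) + 1:
        raise ValueError("too few records for the number of free parameters")

    free = [p for p in _ALL_PARAMS if p not in fixed]
    start = dict(_SINGLE_DEFAULTS)
    start.update(fixed)
    if init:
        start.update(init)

    def build(theta):
        vals = dict(zip(free, theta))
        full = {**start, **fixed, **vals}
        if "c" in vals:
            full["c"] = np.exp(vals["c"])  # optimised as log c
        u = UniversalParams(full["dH_star"], full["dS_star"],
                            full["T_H"], full["T_S"])
        s = StrainParams(full["c"], full["dH_act"], full["dCp"], full["n"])
        return u, s

    def residuals(theta):
        try:
            u, s = build(theta)
        except ValueError:
            return np.full_like(y, 1e6)
        with np.errstate(over="ignore"):
            mu = np.exp(0.5 * log_growth_rate(T, u, s))
        return np.where(np.isfinite(mu), y - mu, 1e6)

    # log-c start matched so the curve passes through the observed peak
    if start["c"] is None:
        u0 = UniversalParams(start["dH_star"], start["dS_star"],
                             start["T_H"], start["T_S"])
        s0 = StrainParams(1.0, start["dH_act"], start["dCp"], start["n"])
        j = int(np.argmax(y))
        start["c"] = float(np.exp(
            2.0 * np.log(max(y[j], 1e-6)) - log_growth_rate(float(T[j]), u0, s0)))

    theta0, lo, hi = [], [], []
    bounds_map = {
        "c": (-np.inf, np.inf), "dH_act": (1e3, 5e5), "dCp": (1.0, 300.0),
        "n": (5.0, 5000.0), "dH_star": (1000.0, 10000.0),
        "dS_star": (1.0, 50.0), "T_H": (300.0, 449.0), "T_S": (300.0, 449.0),
    }
    for p in free:
        theta0.append(np.log(start["c"]) if p == "c" else start[p])
        b = bounds_map[p]
        lo.append(b[0]); hi.append(b[1])

    res = least_squares(residuals, theta0, bounds=(lo, hi), x_scale="jac",
                        method="trf", max_nfev=2000)
    if not res.success:
        raise RuntimeError(
            f"single-strain fit did not converge: {res.message}; "
            f"last iterate {dict(zip(free, res.x))}")
    est = dict(zip(free, res.x))
    if "c" in est:
        est["c"] = float(np.exp(est["c"]))
    params = {**{k: float(v) for k, v in fixed.items()},
              **{k: float(v) for k, v in est.items()}}
    return SingleStrainFit(params=params, fixed=dict(fixed),
                           success=bool(res.success), cost=float(res.cost),
                           nfev=int(res.nfev), message=str(res.message))
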