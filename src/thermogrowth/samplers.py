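"""MCMC building blocks: adaptive Metropolis blocks, adaptive direction
sampling, and highest-posterior-density intervals.

Two proposal mechanisms are provided:

* :class:`HaarioBlock` — adaptive Metropolis in the style of Haario et al.:
  after a fixed-covariance warm-up, proposals are Gaussian with covariance
  ``(2.38^2 / d) * (Sigma_hat + eps I)`` where ``Sigma_hat`` is the running
  empirical covariance of the block's own history.
* :class:`AdaptiveDirectionSampler` — an ensemble of points targeting the
  same (conditional) density; each member moves along the line through two
  other members, scaled as in differential-evolution MCMC, with an
  occasional low-probability "stepping-stone" independence proposal drawn
  from a user-supplied distribution to allow mode jumps.

Both are exact Metropolis samplers (the adaptation is of the standard
diminishing kind) and are used by the hierarchical growth-model sampler
but are generic: they only require a log-density callable.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["HaarioBlock", "AdaptiveDirectionSampler", "hpdi"]


class HaarioBlock:
    """Adaptive-Metropolis update for one parameter block.

    Parameters
    ----------
    init_scale : array-like
        Per-parameter proposal SDs used during warm-up (and as the diagonal
        fallback when the empirical covariance is singular).
    warmup : int
        Number of updates before adaptation switches on.
    jitter : float
        Diagonal regularisation added to the empirical covariance.
    """

    def __init__(self, init_scale, warmup: int = 1000, jitter: float = 1e-10):
        self.init_scale = np.atleast_1d(np.asarray(init_scale, float))
        self.d = len(self.init_scale)
        self.warmup = warmup
        self.jitter = jitter
        self.scale = 2.38 ** 2 / self.d
        self.target_acceptance = 0.234
        # running moments of the block's own chain history
        self._iter = 0
        self._count = 0
        self._mean = np.zeros(self.d)
        self._m2 = np.zeros((self.d, self.d))
        self._log_scale = 0.0  # Robbins-Monro global step-size correction
        self._chol: np.ndarray | None = None
        self.n_proposed = 0
        self.n_accepted = 0

    # -- adaptation ---------------------------------------------------------

    def observe(self, x: np.ndarray) -> None:
        """Fold the current state into the running covariance (Welford)."""
        x = np.asarray(x, float)
        self._iter += 1
        if self._iter == self.warmup:
            # the warm-up trajectory is not stationary; restart the moments
            self._count = 0
            self._mean[:] = 0.0
            self._m2[:] = 0.0
        self._count += 1
        delta = x - self._mean
        self._mean += delta / self._count
        self._m2 += np.outer(delta, x - self._mean)
        self._chol = None  # refresh lazily

    def _adapt_scale(self, accepted: bool) -> None:
        step = 2.0 / max(self._iter, 20) ** 0.6
        self._log_scale += step * ((1.0 if accepted else 0.0)
                                   - self.target_acceptance)
        self._log_scale = float(np.clip(self._log_scale, -10.0, 10.0))
        self._chol = None

    def _proposal_chol(self) -> np.ndarray:
        if self._chol is None:
            mult = np.exp(0.5 * self._log_scale)
            if self._iter <= self.warmup or self._count <= self.d + 1:
                self._chol = mult * np.diag(self.init_scale)
            else:
                cov = self._m2 / (self._count - 1)
                cov = self.scale * np.exp(self._log_scale) * (
                    cov + self.jitter * np.eye(self.d))
                try:
                    self._chol = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    # singular history: diagonal fallback
                    self._chol = mult * np.diag(self.init_scale)
        return self._chol

    # -- Metropolis step ----------------------------------------------------

    def step(self, x: np.ndarray, log_post: Callable[[np.ndarray], float],
             lp_x: float, rng: np.random.Generator
             ) -> tuple[np.ndarray, float, bool]:
        """One Metropolis accept/reject from state ``x`` with density value
        ``lp_x``; returns ``(x_new, lp_new, accepted)``."""
        x = np.asarray(x, float)
        L = self._proposal_chol()
        prop = x + L @ rng.standard_normal(self.d)
        lp_prop = log_post(prop)
        self.n_proposed += 1
        accept = np.isfinite(lp_prop) and (np.log(rng.random()) < lp_prop - lp_x)
        if accept:
            x, lp_x = prop, lp_prop
            self.n_accepted += 1
        self.observe(x)
        self._adapt_scale(bool(accept))
        return x, lp_x, bool(accept)

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_proposed if self.n_proposed else float("nan")


class AdaptiveDirectionSampler:
    """Ensemble sampler moving along directions between ensemble members.

    The ensemble jointly targets the product of ``m`` copies of the same
    density.  For each member ``i`` a proposal is made along the direction
    between two other members ``a, b``:

        x_i' = x_i + gamma * (x_a - x_b),   gamma ~ N(2.38/sqrt(2 d), 0.1^2)

    accepted by the ordinary Metropolis ratio (the move is symmetric).
    With probability ``stepping_stone_prob`` an independence
    ("stepping-stone") proposal drawn from ``stone_sampler`` is used
    instead, enabling jumps to distant regions of the support.
    Member 0 is the ensemble's "current state" for consumers.
    """

    def __init__(self, init_points: np.ndarray,
                 stepping_stone_prob: float = 0.05,
                 stone_sampler: Callable[[np.random.Generator], np.ndarray] | None = None,
                 stone_logpdf: Callable[[np.ndarray], float] | None = None):
        pts = np.asarray(init_points, float)
        if pts.ndim != 2 or pts.shape[0] < 4:
            raise ValueError("need at least 4 ensemble points")
        self.points = pts.copy()
        self.m, self.d = pts.shape
        self.lps = np.full(self.m, np.nan)
        self.gamma0 = 2.38 / np.sqrt(2 * self.d)
        self.stepping_stone_prob = stepping_stone_prob
        if stepping_stone_prob > 0 and (stone_sampler is None or stone_logpdf is None):
            raise ValueError("stepping-stone proposals need a sampler and logpdf")
        self.stone_sampler = stone_sampler
        self.stone_logpdf = stone_logpdf
        self.n_proposed = 0
        self.n_accepted = 0

    @property
    def state(self) -> np.ndarray:
        return self.points[0].copy()

    def invalidate(self) -> None:
        """Mark cached density values stale (the conditional has changed)."""
        self.lps[:] = np.nan

    def step(self, log_post: Callable[[np.ndarray], float],
             rng: np.random.Generator) -> None:
        """One sweep over the ensemble."""
        for i in range(self.m):
            if np.isnan(self.lps[i]):
                self.lps[i] = log_post(self.points[i])
        for i in range(self.m):
            use_stone = (self.stepping_stone_prob > 0
                         and rng.random() < self.stepping_stone_prob)
            if use_stone:
                prop = np.asarray(self.stone_sampler(rng), float)
                log_q_ratio = (self.stone_logpdf(self.points[i])
                               - self.stone_logpdf(prop))
                if not np.isfinite(log_q_ratio):
                    # current point unreachable by the stone proposal:
                    # the reverse density is zero, so always reject
                    self.n_proposed += 1
                    continue
            else:
                a, b = rng.choice([j for j in range(self.m) if j != i],
                                  size=2, replace=False)
                direction = self.points[a] - self.points[b]
                if not np.any(direction):
                    continue  # coincident points: skip the move
                gamma = self.gamma0 * (1.0 + 0.1 * rng.standard_normal())
                prop = self.points[i] + gamma * direction
                log_q_ratio = 0.0
            lp_prop = log_post(prop)
            self.n_proposed += 1
            if not np.isfinite(lp_prop):
                continue
            if (not np.isfinite(self.lps[i])) or (
                    np.log(rng.random()) < lp_prop - self.lps[i] + log_q_ratio):
                self.points[i] = prop
                self.lps[i] = lp_prop
                self.n_accepted += 1

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_proposed if self.n_proposed else float("nan")


def hpdi(samples, level: float = 0.99) -> tuple[float, float]:
    """Highest posterior density interval.

    The shortest contiguous interval containing ``ceil(level * N)`` of the
    sorted samples; ties are broken by the lowest starting point.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    s = np.sort(np.asarray(samples, float))
    n = len(s)
    if n < 2:
        raise ValueError("need at least 2 samples")
    m = int(np.ceil(level * n))
    m = min(max(m, 2), n)
    widths = s[m - 1:] - s[: n - m + 1]
    j = int(np.argmin(widths))  # argmin returns the first (lowest) start
    return float(s[j]), float(s[j + m - 1])
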