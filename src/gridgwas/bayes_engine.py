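"""Bayesian inference on the variance-proportion grid.

Closed-form normal-inverse-gamma marginal likelihoods at each vertex,
grid posteriors of the variance-component proportions, per-marker Bayes
factors, and discretization of continuous priors onto the grid.

Flat (improper) prior components are represented as infinite diagonal
entries of the coefficient prior scale ``Psi`` (zero precision) and as
``a0 = b0 = 0`` for sigma^2.  Their normalizing constants are dropped;
they cancel exactly in posterior ratios and Bayes factors as long as both
compared models share the improper components, which is enforced.

Note: grid posteriors are accurate for summaries such as the posterior
mean, but interval *boundaries* are limited by the grid resolution and
may not be reliable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import gammaln, logsumexp

from .grid_engine import GridScores, GridSpec
from .lmm_core import RotatedModel

__all__ = [
    "NIGPrior",
    "NIGPosterior",
    "PosteriorGrid",
    "BayesFactorResult",
    "nig_marginal_loglik",
    "grid_posterior",
    "bayes_factor",
    "discretize_prior",
]


@dataclass
class NIGPrior:
    """Conjugate prior (theta, sigma^2) ~ NIG(0, Psi sigma^2, a0, b0).

    ``Psi`` is the (c+p) x (c+p) prior covariance scale for the stacked
    coefficients; ``inf`` diagonal entries mark improper flat components.
    ``a0 = b0 = 0`` is the improper flat prior on sigma^2.
    """

    Psi: np.ndarray
    a0: float = 0.0
    b0: float = 0.0

    def __post_init__(self) -> None:
        self.Psi = np.atleast_2d(np.asarray(self.Psi, dtype=float))
        if self.a0 < 0 or self.b0 < 0:
            raise ValueError("a0 and b0 must be non-negative")
        if (self.a0 > 0) != (self.b0 > 0):
            raise ValueError("a0 and b0 must be both zero (improper) or both positive")
        diag = np.diag(self.Psi)
        self.improper = np.isinf(diag)
        off = self.Psi.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(np.isinf(off)):
            raise ValueError("improper components must be diagonal in Psi")
        if self.improper.any() and np.any(off[self.improper][:, ~self.improper]):
            raise ValueError("improper components must be independent of proper ones")

    @classmethod
    def flat_covariates_normal_markers(
        cls, c: int, p: int, psi_marker: float = 1.0
    ) -> "NIGPrior":
        """Flat prior on c covariates and sigma^2, N(0, psi sigma^2) on p markers."""
        diag = np.concatenate([np.full(c, np.inf), np.full(p, psi_marker)])
        return cls(np.diag(diag))

    def precision(self) -> np.ndarray:
        """Zero-filled inverse for improper components."""
        Lam = np.zeros_like(self.Psi)
        prop = ~self.improper
        if prop.any():
            sub = self.Psi[np.ix_(prop, prop)]
            Lam[np.ix_(prop, prop)] = np.linalg.inv(sub)
        return Lam

    def logdet_proper(self) -> float:
        prop = ~self.improper
        if not prop.any():
            return 0.0
        sign, ld = np.linalg.slogdet(self.Psi[np.ix_(prop, prop)])
        if sign <= 0:
            raise ValueError("proper block of Psi is not positive definite")
        return float(ld)


@dataclass
class NIGPosterior:
    Psi_star: np.ndarray
    theta_star: np.ndarray
    a_star: float
    b_star: float
    log_marginal: float
    n_improper: int


def nig_marginal_loglik(rot: RotatedModel, prior: NIGPrior) -> NIGPosterior:
    """Log marginal likelihood of the data at the rotated model's vertex.

    log p(y | h2) = a0 log b0 - lgam(a0) - (n/2) log 2pi - (1/2) log|V|
                    - (1/2) log|Psi| + (1/2) log|Psi*| + lgam(a*) - a* log b*
    with Psi* = (Psi^-1 + X~*^T X~*)^-1, a* = a0 + n/2 and
    b* = b0 + RSS_{y*,Psi}/2.  Constants from improper components are
    dropped (they cancel in ratios of models sharing those components).
    """
    spec = rot.spec
    parts = [rot.W_star]
    if rot.X_star is not None:
        parts.append(rot.X_star)
    D = np.hstack(parts)
    n, k = D.shape
    if prior.Psi.shape != (k, k):
        raise ValueError(f"Psi must be {k} x {k} for this design")
    Lam0 = prior.precision()
    M = Lam0 + D.T @ D
    sign, logdetM = np.linalg.slogdet(M)
    if sign <= 0:
        raise ValueError("posterior precision is singular (rank-deficient design)")
    Psi_star = np.linalg.inv(M)
    u = D.T @ rot.y_star
    theta_star = Psi_star @ u
    rss_psi = float(rot.y_star @ rot.y_star - u @ theta_star)
    a_star = prior.a0 + n / 2.0
    b_star = prior.b0 + rss_psi / 2.0
    log_m = (
        -(n / 2.0) * math.log(2 * math.pi)
        - rot.logdetL  # (1/2) log|V| = log|L|
        - 0.5 * prior.logdet_proper()
        - 0.5 * logdetM
        + gammaln(a_star)
        - a_star * math.log(b_star)
    )
    if prior.a0 > 0:
        log_m += prior.a0 * math.log(prior.b0) - gammaln(prior.a0)
    return NIGPosterior(
        Psi_star, theta_star, a_star, b_star, float(log_m),
        int(prior.improper.sum()),
    )


@dataclass
class PosteriorGrid:
    """Discrete posterior over grid vertices."""

    grid: GridSpec
    log_marginals: np.ndarray
    prior_weights: np.ndarray
    posterior: np.ndarray = field(init=False)
    posterior_mean_h2: np.ndarray = field(init=False)  # length L+1, residual last

    def __post_init__(self) -> None:
        lm = np.asarray(self.log_marginals, dtype=float)
        w = np.asarray(self.prior_weights, dtype=float)
        if lm.shape[0] != self.grid.g or w.shape[0] != self.grid.g:
            raise ValueError("length mismatch with grid")
        if abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("prior weights must sum to 1")
        with np.errstate(divide="ignore"):
            logw = np.where(w > 0, np.log(np.where(w > 0, w, 1.0)), -np.inf)
        score = lm + logw
        finite = np.isfinite(score)
        if not finite.any():
            raise ValueError("all log marginals are -inf; posterior undefined")
        score = np.where(finite, score, -np.inf)
        self.posterior = np.exp(score - logsumexp(score[finite]))
        self.posterior /= self.posterior.sum()
        self.posterior_mean_h2 = self.posterior @ self.grid.as_array()

    def component_nonzero_prob(self) -> np.ndarray:
        """P(h2_l > 0 | y) per random effect: mass off each zero face."""
        arr = self.grid.as_array()[:, : self.grid.L]
        return np.array(
            [self.posterior[arr[:, l] > 0].sum() for l in range(self.grid.L)]
        )

    def credible_set(self, mass: float = 0.95) -> np.ndarray:
        """Smallest set of vertex indices covering at least ``mass``."""
        order = np.argsort(self.posterior)[::-1]
        csum = np.cumsum(self.posterior[order])
        k = int(np.searchsorted(csum, mass) + 1)
        return np.sort(order[:k])

    def to_frame(self):
        import pandas as pd

        arr = self.grid.as_array()
        cols = {f"h2_{l + 1}": arr[:, l] for l in range(self.grid.L)}
        cols["h2_e"] = arr[:, -1]
        cols["prior"] = self.prior_weights
        cols["posterior"] = self.posterior
        return pd.DataFrame(cols)


def grid_posterior(
    grid: GridSpec,
    log_marginals: np.ndarray,
    prior_weights: np.ndarray | None = None,
) -> PosteriorGrid:
    """Normalize per-vertex log marginals into a posterior (log-scale safe)."""
    if prior_weights is None:
        prior_weights = np.full(grid.g, 1.0 / grid.g)
    return PosteriorGrid(grid, np.asarray(log_marginals, float), prior_weights)


@dataclass
class BayesFactorResult:
    log10_BF: np.ndarray  # one per test
    alt_log_marginals: np.ndarray  # (tests, vertices)
    null_log_marginals: np.ndarray  # (vertices,)
    prior_weights: np.ndarray

    def __post_init__(self) -> None:
        self.log10_BF = np.atleast_1d(np.asarray(self.log10_BF, dtype=float))


def bayes_factor(
    alt: GridScores,
    null: GridScores | np.ndarray,
    prior_weights: np.ndarray | None = None,
) -> BayesFactorResult:
    """Grid-averaged Bayes factor per test.

    BF = [sum_h2 p(y | h2, alt) p(h2)] / [sum_h2 p(y | h2, null) p(h2)],
    assembled by log-sum-exp.  Alt and null must be evaluated on the same
    vertex set and prior.  Vertices unevaluated (NaN) in *either* model are
    excluded from both sums so the comparison stays symmetric.
    """
    alt_lm = alt.scores
    null_lm = null.scores.ravel() if isinstance(null, GridScores) else np.ravel(null)
    g = alt_lm.shape[1]
    if null_lm.shape[0] != g:
        raise ValueError("alt and null were not computed on the same grid")
    if isinstance(null, GridScores):
        if len(null.vertices) != len(alt.vertices) or any(
            a.h2 != b.h2 for a, b in zip(alt.vertices, null.vertices)
        ):
            raise ValueError("alt and null were not computed on the same grid")
    if prior_weights is None:
        prior_weights = np.full(g, 1.0 / g)
    prior_weights = np.asarray(prior_weights, dtype=float)
    with np.errstate(divide="ignore"):
        logw = np.where(prior_weights > 0, np.log(np.maximum(prior_weights, 1e-300)), -np.inf)
    log10_bf = np.empty(alt_lm.shape[0])
    for t in range(alt_lm.shape[0]):
        mask = np.isfinite(alt_lm[t]) & np.isfinite(null_lm) & np.isfinite(logw)
        if not mask.any():
            log10_bf[t] = np.nan
            continue
        la = logsumexp(alt_lm[t][mask] + logw[mask])
        ln = logsumexp(null_lm[mask] + logw[mask])
        log10_bf[t] = (la - ln) / math.log(10.0)
    return BayesFactorResult(log10_bf, alt_lm, null_lm, prior_weights)


def discretize_prior(
    target: Callable,
    grid: GridSpec,
    n_draws: int = 10_000,
    mode: str = "sampler",
    rng: np.random.Generator | int | None = None,
    subdivisions: int = 4,
) -> np.ndarray:
    """Approximate a continuous prior on h2 by per-vertex weights.

    mode="sampler": ``target(rng, size)`` returns draws of either standard
    deviations (L+1 columns, converted to proportions sd^2 / sum sd^2) or
    proportions (L columns); each draw is assigned to the nearest vertex
    and weights are the assignment frequencies.  Out-of-simplex proportion
    draws are renormalized onto the simplex and counted.

    mode="density": ``target(h2_row) -> density``; each vertex receives the
    midpoint-rule integral of the density over the full step-width
    rectangle centred on it (the density must vanish outside its own
    support), then weights are normalized.
    """
    V = grid.as_array()[:, : grid.L]
    g = grid.g
    if mode == "density":
        step = 1.0 / grid.m
        offs = (np.arange(subdivisions) + 0.5) / subdivisions - 0.5
        import itertools as it

        weights = np.zeros(g)
        for i, v in enumerate(V):
            tot = 0.0
            for combo in it.product(offs, repeat=grid.L):
                tot += float(target(v + step * np.array(combo)))
            weights[i] = tot
        if weights.sum() <= 0:
            raise ValueError("density integrates to zero over the grid")
        return weights / weights.sum()
    if mode != "sampler":
        raise ValueError(f"unknown mode {mode!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    draws = np.asarray(target(rng, n_draws), dtype=float)
    if draws.ndim != 2:
        raise ValueError("sampler must return a 2-D array of draws")
    if draws.shape[1] == grid.L + 1:  # standard deviations, residual last
        var = draws**2
        props = var[:, : grid.L] / var.sum(axis=1, keepdims=True)
    elif draws.shape[1] == grid.L:
        props = draws
    else:
        raise ValueError("sampler draws must have L or L+1 columns")
    bad = (props < 0).any(axis=1) | (props.sum(axis=1) > 1.0)
    if bad.any():
        clipped = np.clip(props[bad], 0.0, None)
        tot = clipped.sum(axis=1, keepdims=True)
        scale = np.where(tot > 1.0, (1.0 - 1e-9) / tot, 1.0)
        props[bad] = clipped * scale
    # nearest-vertex assignment (Euclidean in the L proportion coordinates)
    counts = np.zeros(g)
    chunk = 4096
    for start in range(0, props.shape[0], chunk):
        block = props[start : start + chunk]
        d2 = ((block[:, None, :] - V[None, :, :]) ** 2).sum(axis=2)
        nearest = np.argmin(d2, axis=1)
        counts += np.bincount(nearest, minlength=g)
    weights = counts / counts.sum()
    weights.flags.writeable = True
    return weights
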