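"""Conditional linear-model algebra at a fixed variance-proportion vertex.

Given proportions ``h2 = (h2_1, ..., h2_L, h2_e)`` on the simplex, the
marginal covariance ``V = sum_l h2_l Z_l K_l Z_l^T + h2_e I`` is assembled
and factored once (lower Cholesky ``V = C C^T``); the response and all
design columns are whitened by triangular solves and every downstream fit
is ordinary least squares on the rotated data.  ML and REML profile
log-likelihoods, Wald F tests and likelihood-ratio tests are computed from
the rotated fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import stats

from .kinships import IncidenceMap, RelationshipMatrix

__all__ = [
    "ModelSpec",
    "GridVertex",
    "RotatedModel",
    "GLSFit",
    "TestResult",
    "RotationError",
    "rotate_model",
    "fit_gls",
    "profile_loglik",
    "wald_test",
    "likelihood_ratio_test",
]


class RotationError(RuntimeError):
    """Covariance at a vertex is not positive definite."""


@dataclass(frozen=True)
class GridVertex:
    """One point on the variance-component-proportion simplex.

    ``h2`` holds the L random-effect proportions; ``he2`` is the residual
    proportion.  Entries are non-negative and sum to one with ``he2 > 0``.
    """

    h2: tuple[float, ...]

    def __post_init__(self) -> None:
        h2 = tuple(float(v) for v in self.h2)
        object.__setattr__(self, "h2", h2)
        if any(v < 0 for v in h2):
            raise ValueError(f"negative variance proportion in {h2}")
        if sum(h2) >= 1.0 - 1e-12:
            raise ValueError(f"proportions {h2} leave no residual variance")

    @property
    def he2(self) -> float:
        return 1.0 - sum(self.h2)

    @property
    def L(self) -> int:
        return len(self.h2)

    def as_array(self) -> np.ndarray:
        return np.array(self.h2)


@dataclass
class ModelSpec:
    """Observed-data model: response, designs and random-effect kernels.

    ``random_effects`` is an ordered list of ``(Z, K)`` pairs; ``Z`` may be
    None when observations map one-to-one onto the rows of ``K``.
    """

    y: np.ndarray  # (n,)
    W: np.ndarray  # (n, c) covariates incl. intercept
    X: np.ndarray | None = None  # (n, p) marker design, optional
    random_effects: list[tuple[IncidenceMap | None, RelationshipMatrix]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        n = self.y.shape[0]
        if self.W.shape[0] != n:
            raise ValueError("W row count does not match response length")
        if self.X is not None:
            self.X = np.asarray(self.X, dtype=float)
            if self.X.ndim == 1:
                self.X = self.X[:, None]
            if self.X.shape[0] != n:
                raise ValueError("X row count does not match response length")
        if np.isnan(self.y).any() or np.isnan(self.W).any():
            raise ValueError("missing values in response or covariates")
        if np.linalg.matrix_rank(self.W) < self.W.shape[1]:
            raise ValueError("covariate design W is rank deficient")
        self._covs = None

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def c(self) -> int:
        return self.W.shape[1]

    @property
    def p(self) -> int:
        return 0 if self.X is None else self.X.shape[1]

    @property
    def L(self) -> int:
        return len(self.random_effects)

    def re_covariances(self) -> list[np.ndarray]:
        """Observation-level n x n covariance Z_l K_l Z_l^T per random effect."""
        if self._covs is None:
            covs = []
            for Z, K in self.random_effects:
                if Z is None:
                    if K.n != self.n:
                        raise ValueError(
                            "kinship size does not match n and no incidence map given"
                        )
                    covs.append(K.values)
                else:
                    codes = Z._codes
                    covs.append(K.values[np.ix_(codes, codes)])
            self._covs = covs
        return self._covs

    def without_markers(self) -> "ModelSpec":
        return ModelSpec(self.y, self.W, None, self.random_effects)

    def with_response(self, y: np.ndarray) -> "ModelSpec":
        return ModelSpec(y, self.W, self.X, self.random_effects)


def assemble_covariance(spec: ModelSpec, vertex: GridVertex) -> np.ndarray:
    """V = sum_l h2_l Z_l K_l Z_l^T + h2_e I."""
    if vertex.L != spec.L:
        raise ValueError(
            f"vertex has {vertex.L} proportions but model has {spec.L} random effects"
        )
    V = vertex.he2 * np.eye(spec.n)
    for h2_l, cov in zip(vertex.h2, spec.re_covariances()):
        if h2_l:
            V = V + h2_l * cov
    return V


@dataclass
class RotatedModel:
    """Whitened model at one vertex, reusable across marker columns."""

    spec: ModelSpec
    vertex: GridVertex
    chol: np.ndarray  # lower Cholesky factor of V
    logdetL: float
    y_star: np.ndarray
    W_star: np.ndarray
    X_star: np.ndarray | None

    def rotate(self, cols: np.ndarray) -> np.ndarray:
        """Whiten additional (n, k) columns with the stored factor."""
        return sla.solve_triangular(self.chol, cols, lower=True)


def rotate_model(spec: ModelSpec, vertex: GridVertex) -> RotatedModel:
    """Assemble V at the vertex, factor it once, and whiten y, W and X."""
    V = assemble_covariance(spec, vertex)
    try:
        C = sla.cholesky(V, lower=True)
    except sla.LinAlgError as exc:
        raise RotationError(
            f"covariance not positive definite at vertex h2={vertex.h2}"
        ) from exc
    logdetL = float(np.sum(np.log(np.diag(C))))
    cols = [spec.y[:, None], spec.W]
    if spec.X is not None:
        cols.append(spec.X)
    rotated = sla.solve_triangular(C, np.hstack(cols), lower=True)
    y_star = rotated[:, 0]
    W_star = rotated[:, 1 : 1 + spec.c]
    X_star = rotated[:, 1 + spec.c :] if spec.X is not None else None
    return RotatedModel(spec, vertex, C, logdetL, y_star, W_star, X_star)


@dataclass
class GLSFit:
    """GLS solution on rotated data plus the pieces of the profile likelihoods."""

    rot: RotatedModel
    alpha_hat: np.ndarray
    beta_hat: np.ndarray
    sigma2_ml: float
    sigma2_reml: float
    RSS: float
    xtx_inv: np.ndarray | None  # (c+p, c+p) = (X~^T V^-1 X~)^-1
    logdet_gram_star: float  # log |X~*^T X~*|
    logdet_gram_raw: float  # log |X~^T X~|
    n: int
    c: int
    p: int
    flag: str | None = None  # 'rank_deficient' | 'perfect_fit' | None

    @property
    def ok(self) -> bool:
        return self.flag is None

    @property
    def logLik_ML(self) -> float:
        return profile_loglik(self.rot, self, kind="ML")

    @property
    def logLik_REML(self) -> float:
        return profile_loglik(self.rot, self, kind="REML")


def _logdet_gram(A: np.ndarray) -> float:
    sign, val = np.linalg.slogdet(A.T @ A)
    return float(val) if sign > 0 else -np.inf


def fit_gls(
    rot: RotatedModel,
    marker_cols: np.ndarray | None = None,
    marker_cols_raw: np.ndarray | None = None,
) -> GLSFit:
    """Least squares on the rotated data.

    ``marker_cols`` are additional already-rotated design columns appended
    after the spec's own X; ``marker_cols_raw`` are their unrotated
    counterparts (needed only for the REML determinant correction).  Rank
    deficiency yields a flagged fit rather than an exception so scans can
    skip the test.
    """
    spec = rot.spec
    design_parts = [rot.W_star]
    raw_parts = [spec.W]
    if rot.X_star is not None:
        design_parts.append(rot.X_star)
        raw_parts.append(spec.X)
    if marker_cols is not None:
        mc = marker_cols if marker_cols.ndim == 2 else marker_cols[:, None]
        design_parts.append(mc)
        if marker_cols_raw is not None:
            raw = marker_cols_raw if marker_cols_raw.ndim == 2 else marker_cols_raw[:, None]
            raw_parts.append(raw)
        else:
            raw_parts = None
    design = np.hstack(design_parts)
    n, k = design.shape
    c = spec.c
    p = k - c
    theta, _, rank, _ = np.linalg.lstsq(design, rot.y_star, rcond=None)
    if rank < k:
        return GLSFit(
            rot, theta[:c] * np.nan, theta[c:] * np.nan, np.nan, np.nan, np.nan,
            None, np.nan, np.nan, n, c, p, flag="rank_deficient",
        )
    resid = rot.y_star - design @ theta
    RSS = float(resid @ resid)
    gram = design.T @ design
    xtx_inv = np.linalg.inv(gram)
    logdet_gram_star = _logdet_gram(design)
    if raw_parts is not None:
        logdet_gram_raw = _logdet_gram(np.hstack(raw_parts))
    else:
        logdet_gram_raw = np.nan
    sigma2_ml = RSS / n
    df = n - k
    sigma2_reml = RSS / df if df > 0 else np.nan
    flag = "perfect_fit" if RSS <= 1e-12 * float(rot.y_star @ rot.y_star) else None
    return GLSFit(
        rot, theta[:c], theta[c:], sigma2_ml, sigma2_reml, RSS,
        xtx_inv, logdet_gram_star, logdet_gram_raw, n, c, p, flag=flag,
    )


def profile_loglik(rot: RotatedModel, fit: GLSFit, kind: str = "REML") -> float:
    """Profile log-likelihood of the variance proportions at this vertex.

    ML:    (n/2) [log(n / 2 pi) - 1 - log RSS] - log|L|
    REML:  (d/2) [log(d / 2 pi) - 1 - log RSS] - log|L|
           + (1/2) log|X~^T X~| - (1/2) log|X~*^T X~*|,   d = n - c - p,
    i.e. the full likelihood evaluated at the profiled coefficients and
    the corresponding sigma^2 estimate, with the REML determinant
    correction.
    """
    if not fit.ok and fit.flag != "perfect_fit":
        return np.nan
    n = fit.n
    if fit.RSS <= 0 or fit.flag == "perfect_fit":
        # degenerate fit: excluded from maximization rather than dominating it
        return -math.inf
    if kind == "ML":
        return (n / 2.0) * (math.log(n / (2 * math.pi)) - 1.0 - math.log(fit.RSS)) - rot.logdetL
    if kind == "REML":
        d = n - fit.c - fit.p
        if d <= 0:
            raise ValueError("no residual degrees of freedom for REML")
        if math.isnan(fit.logdet_gram_raw):
            raise ValueError(
                "REML profile requires unrotated design columns (marker_cols_raw)"
            )
        return (
            (d / 2.0) * (math.log(d / (2 * math.pi)) - 1.0 - math.log(fit.RSS))
            - rot.logdetL
            + 0.5 * (fit.logdet_gram_raw - fit.logdet_gram_star)
        )
    raise ValueError(f"unknown likelihood kind {kind!r}")


@dataclass
class TestResult:
    statistic: float
    df1: int
    df2: int
    p_value: float
    tested_contrast: str
    flag: str | None = None


def wald_test(fit: GLSFit, M: np.ndarray, df2: int | None = None) -> TestResult:
    """General Wald F test of M theta = 0 for theta = [alpha; beta].

    F = theta^T M^T (M (X~^T V^-1 X~)^-1 M^T)^-1 M theta / (q sigma2_REML),
    referred to F(q, n - c - p).
    """
    if not fit.ok:
        return TestResult(np.nan, 0, 0, np.nan, "flagged fit", flag=fit.flag)
    M = np.atleast_2d(np.asarray(M, dtype=float))
    q = M.shape[0]
    theta = np.concatenate([fit.alpha_hat, fit.beta_hat])
    if M.shape[1] != theta.shape[0]:
        raise ValueError("contrast width does not match coefficient count")
    if df2 is None:
        df2 = fit.n - fit.c - fit.p
    mid = M @ fit.xtx_inv @ M.T
    try:
        sol = np.linalg.solve(mid, M @ theta)
    except np.linalg.LinAlgError:
        return TestResult(np.nan, q, df2, np.nan, "singular contrast", flag="singular")
    F = float((M @ theta) @ sol) / (q * fit.sigma2_reml)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, q, df2))
    return TestResult(F, q, df2, p, f"M theta = 0, q={q}")


def likelihood_ratio_test(ml_null: float, ml_alt: float, df: int) -> TestResult:
    """Chi-square LRT from two ML profile log-likelihoods (null nested in alt)."""
    stat = 2.0 * (ml_alt - ml_null)
    flag = None
    if stat < -1e-6:
        warnings.warn(
            f"alternative log-likelihood below null by {-stat / 2:.3g}; "
            "grid may be too coarse",
            RuntimeWarning,
        )
        flag = "alt_below_null"
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df))
    return TestResult(stat, df, 0, p, f"LRT df={df}", flag=flag)
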