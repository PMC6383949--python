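"""Simplex grid over variance-component proportions and the full grid scan.

The grid places vertices at integer multiples of ``1/m`` with all
proportions non-negative and their sum strictly below one (so the
residual proportion stays positive and the covariance stays positive
definite).  A scan factors the covariance once per vertex and reuses the
whitened design across every marker (or trait), so the number of Cholesky
factorizations equals the number of vertices regardless of the number of
tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from . import lmm_core
from .lmm_core import GridVertex, ModelSpec, RotatedModel

__all__ = [
    "GridSpec",
    "GridScores",
    "grid_size",
    "build_grid",
    "grid_search",
    "VertexEvaluator",
]

_SIMPLEX_EPS = 1e-9


def grid_size(L: int, m: int) -> int:
    """Number of vertices of the step-1/m grid with L proportions.

    Closed form: sum_{k=1}^{L} C(m, k) C(L-1, k-1), which equals
    C(m+L-1, L) — the count of lattice points with nonnegative
    coordinates summing to at most (m-1)/m, origin included.
    """
    if L < 1 or m < 1:
        raise ValueError("L and m must be >= 1")
    return sum(math.comb(m, k) * math.comb(L - 1, k - 1) for k in range(1, L + 1))


@dataclass
class GridSpec:
    """Ordered (lexicographic) list of simplex grid vertices."""

    L: int
    m: int
    peg: GridVertex | None
    vertices: list[GridVertex]

    @property
    def g(self) -> int:
        return len(self.vertices)

    def as_array(self) -> np.ndarray:
        """(g, L+1) array of proportions, residual proportion last."""
        arr = np.array([list(v.h2) + [v.he2] for v in self.vertices])
        return arr

    def index_of(self, vertex: GridVertex, tol: float = 1e-9) -> int:
        for i, v in enumerate(self.vertices):
            if max(abs(a - b) for a, b in zip(v.h2, vertex.h2)) < tol:
                return i
        raise KeyError(f"vertex {vertex.h2} not in grid")


def build_grid(L: int, m: int, peg: GridVertex | None = None) -> GridSpec:
    """Rectangular step-1/m grid, pegged to the origin or to a given vertex.

    A pegged grid is the origin grid translated so that one vertex lies at
    ``peg``, with out-of-simplex vertices clipped.
    """
    if L < 1 or m < 1:
        raise ValueError("L and m must be >= 1")
    if peg is None:
        offsets = [0.0] * L
    else:
        if peg.L != L:
            raise ValueError("peg dimension does not match L")
        offsets = [p - math.floor(p * m + _SIMPLEX_EPS) / m for p in peg.h2]
    step = 1.0 / m
    ranges = []
    for off in offsets:
        lo = math.ceil(-off / step - _SIMPLEX_EPS)
        hi = math.floor((1.0 - off) / step + _SIMPLEX_EPS)
        ranges.append(range(lo, hi + 1))
    vertices = []
    for combo in itertools.product(*ranges):
        coords = tuple(off + j * step for off, j in zip(offsets, combo))
        if any(c < -_SIMPLEX_EPS for c in coords):
            continue
        coords = tuple(max(c, 0.0) for c in coords)
        if sum(coords) >= 1.0 - _SIMPLEX_EPS:
            continue
        vertices.append(GridVertex(coords))
    vertices.sort(key=lambda v: v.h2)
    return GridSpec(L, m, peg, vertices)


@dataclass
class GridScores:
    """Per-test, per-vertex scores with lexicographic-first argmax."""

    test_labels: list[str]
    vertices: list[GridVertex]
    scores: np.ndarray  # (tests, vertices); NaN where not evaluated
    criterion: str
    best_idx: np.ndarray = field(init=False)
    best_score: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        with np.errstate(invalid="ignore"):
            all_nan = np.all(np.isnan(self.scores), axis=1)
            safe = np.where(np.isnan(self.scores), -np.inf, self.scores)
            self.best_idx = np.argmax(safe, axis=1)
            self.best_idx[all_nan] = -1
            self.best_score = np.where(
                all_nan, np.nan, safe[np.arange(safe.shape[0]), self.best_idx]
            )

    def best_vertex(self, test: int) -> GridVertex:
        idx = self.best_idx[test]
        if idx < 0:
            raise ValueError(f"test {test} has no evaluated vertex")
        return self.vertices[idx]


class VertexEvaluator:
    """Evaluates per-test scores at grid vertices, one rotation per vertex.

    In per-marker mode each test appends a block of ``q`` marker columns to
    the shared covariate design ``W``.  In per-trait mode each test swaps in
    a different response with the same design.  Criteria: ``REML`` / ``ML``
    profile log-likelihoods or the ``marginal`` (NIG) log marginal
    likelihood with a flat improper prior on the covariates and sigma^2 and
    a conditional N(0, psi_marker sigma^2) prior per marker coefficient.
    """

    def __init__(
        self,
        spec: ModelSpec,
        marker_blocks: np.ndarray | None = None,
        traits: np.ndarray | None = None,
        responses: np.ndarray | None = None,
        criterion: str = "REML",
        psi_marker: float = 1.0,
        a0: float = 0.0,
        b0: float = 0.0,
    ) -> None:
        if spec.X is not None:
            raise ValueError("pass marker columns via marker_blocks, not spec.X")
        if marker_blocks is not None and traits is not None:
            raise ValueError("marker_blocks and traits are mutually exclusive")
        if responses is not None and marker_blocks is None:
            raise ValueError("paired responses require marker_blocks")
        if criterion not in ("REML", "ML", "marginal"):
            raise ValueError(f"unknown criterion {criterion!r}")
        self.spec = spec
        self.criterion = criterion
        self.psi_marker = float(psi_marker)
        self.a0 = float(a0)
        self.b0 = float(b0)
        self.n_rotations = 0
        n, c = spec.n, spec.c
        if marker_blocks is not None:
            Xb = np.asarray(marker_blocks, dtype=float)
            if Xb.ndim == 2:  # (n, p) single-column tests
                Xb = Xb.T[:, :, None]
            if Xb.shape[1] != n:
                raise ValueError("marker blocks must be shaped (p, n, q)")
            self.Xb = Xb
            self.p, _, self.q = Xb.shape
            self.n_tests = self.p
            # paired mode: test j regresses its own response column on block j
            self.Y = None
            if responses is not None:
                self.Y = np.asarray(responses, dtype=float)
                if self.Y.shape != (n, self.p):
                    raise ValueError("responses must be shaped (n, p)")
        else:
            self.Xb = None
            self.q = 0
            if traits is None:
                traits = spec.y[:, None]
            self.traits = np.asarray(traits, dtype=float)
            if self.traits.ndim == 1:
                self.traits = self.traits[:, None]
            self.n_tests = self.traits.shape[1]
        if criterion == "REML":
            self._raw_logdets = self._raw_gram_logdets()
        self._cache: dict[tuple[float, ...], dict] = {}

    # -- internals ---------------------------------------------------------

    def _residualize(self, Q: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return cols - Q @ (Q.T @ cols)

    def _raw_gram_logdets(self) -> np.ndarray | float:
        """log |X~^T X~| for the unrotated design of every test."""
        W = self.spec.W
        Q, R = np.linalg.qr(W)
        logdet_W = 2.0 * float(np.sum(np.log(np.abs(np.diag(R)))))
        if self.Xb is None:
            return logdet_W
        Xr = self._residualize(Q, self._flat_markers())
        A = self._block_grams(Xr)
        sign, ld = np.linalg.slogdet(A)
        out = logdet_W + np.where(sign > 0, ld, -np.inf)
        return out

    def _flat_markers(self) -> np.ndarray:
        # (n, p*q) column-flattened marker blocks
        return self.Xb.transpose(1, 0, 2).reshape(self.spec.n, self.p * self.q)

    def _block_grams(self, Xr_flat: np.ndarray) -> np.ndarray:
        X3 = Xr_flat.reshape(self.spec.n, self.p, self.q)
        return np.einsum("npq,npr->pqr", X3, X3)

    def _vertex_state(self, vertex: GridVertex) -> dict:
        key = vertex.h2
        if key in self._cache:
            return self._cache[key]
        rot = lmm_core.rotate_model(self.spec, vertex)
        self.n_rotations += 1
        Q, R = np.linalg.qr(rot.W_star)
        logdet_Wstar = 2.0 * float(np.sum(np.log(np.abs(np.diag(R)))))
        # only light summaries are retained; the factor itself is discarded
        state: dict = {"logdetL": rot.logdetL, "logdet_Wstar": logdet_Wstar}
        if self.Xb is not None:
            Xs = rot.rotate(self._flat_markers())
            Xr = self._residualize(Q, Xs)
            X3 = Xr.reshape(self.spec.n, self.p, self.q)
            state["A"] = np.einsum("npq,npr->pqr", X3, X3)
            if self.Y is None:
                y_r = self._residualize(Q, rot.y_star[:, None]).ravel()
                state["RSS0"] = float(y_r @ y_r)
                state["b"] = np.einsum("npq,n->pq", X3, y_r)
            else:
                Yr = self._residualize(Q, rot.rotate(self.Y))
                state["RSS0"] = np.einsum("np,np->p", Yr, Yr)
                state["b"] = np.einsum("npq,np->pq", X3, Yr)
        else:
            Ys = rot.rotate(self.traits)
            Yr = self._residualize(Q, Ys)
            state["RSS_t"] = np.einsum("nt,nt->t", Yr, Yr)
        if len(self._cache) >= 256:  # bounded: heuristic searches revisit vertices
            self._cache.pop(next(iter(self._cache)))
        self._cache[key] = state
        return state

    def _marker_rss(self, state: dict, ridge: float = 0.0):
        """Per-marker RSS (optionally ridged) and log|A (+ ridge I)|."""
        A = state["A"]
        if ridge:
            A = A + ridge * np.eye(self.q)
        b = state["b"]
        sign, logdetA = np.linalg.slogdet(A)
        ok = sign > 0
        theta = np.full_like(b, np.nan)
        if ok.all():
            theta = np.linalg.solve(A, b[..., None])[..., 0]
        else:
            theta[ok] = np.linalg.solve(A[ok], b[ok][..., None])[..., 0]
        quad = np.einsum("pq,pq->p", b, theta)
        RSS = state["RSS0"] - quad
        RSS = np.where(ok, np.maximum(RSS, 0.0), np.nan)
        logdetA = np.where(ok, logdetA, np.nan)
        return RSS, logdetA, theta, A, ok

    # -- public API --------------------------------------------------------

    def scores(self, vertex: GridVertex) -> np.ndarray:
        """Score every test at one vertex (shape: (n_tests,))."""
        state = self._vertex_state(vertex)
        n, c = self.spec.n, self.spec.c
        logdetL = state["logdetL"]
        if self.Xb is None:
            RSS = state["RSS_t"]
            k = c
        else:
            if self.criterion == "marginal":
                return self._marginal_scores(state)
            RSS, logdetA, _, _, ok = self._marker_rss(state)
            k = c + self.q
        with np.errstate(divide="ignore", invalid="ignore"):
            logRSS = np.log(RSS)
        if self.criterion == "ML":
            out = (n / 2.0) * (math.log(n / (2 * math.pi)) - 1.0 - logRSS) - logdetL
        elif self.criterion == "REML":
            d = n - k
            out = (
                (d / 2.0) * (math.log(d / (2 * math.pi)) - 1.0 - logRSS)
                - logdetL
                + 0.5 * self._raw_logdets
                - 0.5 * state["logdet_Wstar"]
            )
            if self.Xb is not None:
                out = out - 0.5 * logdetA
        else:  # marginal, trait mode
            return self._marginal_scores(state)
        if np.ndim(out) == 0:
            out = np.full(self.n_tests, float(out))
        return np.asarray(out, dtype=float)

    def _marginal_scores(self, state: dict) -> np.ndarray:
        """Log marginal likelihood per test (flat alpha/sigma^2 prior).

        Improper flat components contribute a constant shared by every
        model with the same covariates; it is dropped, so these values are
        comparable across vertices and across nested marker models only.
        """
        n = self.spec.n
        a_star = self.a0 + n / 2.0
        base = (
            -(n / 2.0) * math.log(2 * math.pi)
            - state["logdetL"]
            - 0.5 * state["logdet_Wstar"]
            + gammaln(a_star)
        )
        if self.a0 > 0:
            base += self.a0 * math.log(self.b0)
            base -= gammaln(self.a0)
        if self.Xb is None:
            b_star = self.b0 + state["RSS_t"] / 2.0
            return base - a_star * np.log(b_star)
        psi = self.psi_marker
        RSS_psi, logdetApen, _, _, _ = self._marker_rss(state, ridge=1.0 / psi)
        b_star = self.b0 + RSS_psi / 2.0
        return (
            base
            - (self.q / 2.0) * math.log(psi)
            - 0.5 * logdetApen
            - a_star * np.log(b_star)
        )

    def null_marginal(self, vertex: GridVertex) -> float:
        """Log marginal of the covariate-only (no marker) model at a vertex."""
        state = self._vertex_state(vertex)
        n = self.spec.n
        a_star = self.a0 + n / 2.0
        rss0 = state["RSS0"] if self.Xb is not None else float(state["RSS_t"][0])
        # paired responses yield one null marginal per test
        if self.Xb is not None and self.Y is not None:
            rss0 = np.asarray(state["RSS0"])
        base = (
            -(n / 2.0) * math.log(2 * math.pi)
            - state["logdetL"]
            - 0.5 * state["logdet_Wstar"]
            + gammaln(a_star)
        )
        if self.a0 > 0:
            base += self.a0 * math.log(self.b0) - gammaln(self.a0)
        return base - a_star * np.log(self.b0 + rss0 / 2.0)

    def wald_stats(self, vertex: GridVertex, idx: np.ndarray, contrast_col: int = 0):
        """Effect, SE and Wald F for one marker-block column, per test.

        Returns arrays (beta, se, F, df2) for the tests in ``idx`` with the
        contrast selecting column ``contrast_col`` of each marker block.
        """
        if self.Xb is None:
            raise ValueError("wald_stats requires per-marker mode")
        state = self._vertex_state(vertex)
        n, c, q = self.spec.n, self.spec.c, self.q
        RSS, _, theta, A, ok = self._marker_rss(state)
        d = n - c - q
        sub = np.asarray(idx)
        with np.errstate(divide="ignore", invalid="ignore"):
            sigma2 = RSS[sub] / d
            Ainv = np.full_like(A[sub], np.nan)
            Ainv[ok[sub]] = np.linalg.inv(A[sub][ok[sub]])
            var = sigma2 * Ainv[:, contrast_col, contrast_col]
            beta = theta[sub, contrast_col]
            se = np.sqrt(var)
            F = beta**2 / var
        return beta, se, F, d


def grid_search(
    spec: ModelSpec,
    grid: GridSpec,
    markers: np.ndarray | None = None,
    criterion: str = "REML",
    tests: str = "per-marker",
    test_labels: list[str] | None = None,
    psi_marker: float = 1.0,
    max_cells: float = 5e7,
    evaluator: "VertexEvaluator | None" = None,
) -> GridScores:
    """Score every test at every grid vertex (full, non-heuristic search)."""
    if evaluator is not None:
        ev = evaluator
        criterion = ev.criterion
    elif tests == "per-marker":
        if markers is None:
            raise ValueError("per-marker search requires marker columns")
        ev = VertexEvaluator(
            spec, marker_blocks=markers, criterion=criterion, psi_marker=psi_marker
        )
    elif tests == "per-trait":
        ev = VertexEvaluator(spec, traits=markers, criterion=criterion)
    else:
        raise ValueError(f"unknown test mode {tests!r}")
    if ev.n_tests * grid.g > max_cells:
        raise MemoryError(
            f"score matrix {ev.n_tests} x {grid.g} exceeds max_cells={max_cells:g}"
        )
    S = np.empty((ev.n_tests, grid.g))
    for j, v in enumerate(grid.vertices):
        S[:, j] = ev.scores(v)
    if test_labels is None:
        test_labels = [f"t{i}" for i in range(ev.n_tests)]
    return GridScores(test_labels, list(grid.vertices), S, criterion)
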