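"""Genome-wide scans, G-by-E designs and calibration diagnostics.

Orchestrates per-marker association scans (Wald, likelihood-ratio or
Bayes-factor) over the variance-proportion grid, multi-trait
variance-component estimation, and genomic-control inflation factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import fast_search
from .bayes_engine import grid_posterior
from .grid_engine import GridScores, GridSpec, VertexEvaluator, build_grid, grid_search
from .kinships import GenotypeMatrix
from .lmm_core import GridVertex, ModelSpec

__all__ = [
    "ScanConfig",
    "AssociationTable",
    "GCResult",
    "run_association_scan",
    "build_gxe_design",
    "genomic_control",
    "variance_component_scan",
]

#: fixed output column order of an association table
TABLE_COLUMNS = ("marker", "chrom", "pos", "beta", "se", "F", "df1", "df2", "p")


@dataclass
class ScanConfig:
    """Settings of one association scan."""

    method: str = "wald"  # wald | lrt | bayes
    search: str = "fast"  # full | fast | null (variance fixed at null estimate)
    m: int = 100  # grid divisions (step 1/m)
    peg: str = "null"  # null | origin
    psi_marker: float = 1.0  # prior variance scale of marker effects (bayes)
    genomic_control: bool = True  # report lambda (never silently applied)
    threshold: float = 2e-7  # Bonferroni-style genome-wide level
    standardize: bool = False
    max_cells: float = 5e7
    ring_stop_fraction: float = 1e-4

    def __post_init__(self) -> None:
        if self.method not in ("wald", "lrt", "bayes"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.search not in ("full", "fast", "null"):
            raise ValueError(f"unknown search {self.search!r}")
        if not (0 < self.threshold < 1):
            raise ValueError("significance threshold must be in (0, 1)")


@dataclass
class AssociationTable:
    """Per-marker scan results plus scan-level metadata."""

    frame: pd.DataFrame
    config: ScanConfig
    h0: GridVertex | None = None
    gc: "GCResult | None" = None
    trace: object | None = None

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class GCResult:
    """Genomic-control inflation factor and rescaled statistics."""

    lambda_: float
    df1: int
    df2: int
    corrected: np.ndarray

    def __post_init__(self) -> None:
        if not self.lambda_ > 0:
            raise ValueError("inflation factor must be positive")

    def corrected_pvalues(self) -> np.ndarray:
        return stats.f.sf(self.corrected, self.df1, self.df2)


def _marker_array(markers) -> tuple[np.ndarray, list[str], np.ndarray | None, np.ndarray | None]:
    if isinstance(markers, GenotypeMatrix):
        return markers.dosages, list(markers.markers), markers.chrom, markers.pos
    arr = np.asarray(markers, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"m{j}" for j in range(arr.shape[1])], None, None


def build_marker_blocks(
    dosages: np.ndarray, env: np.ndarray | None = None, standardize: bool = False
) -> tuple[np.ndarray, int]:
    """(p, n, q) per-test design blocks and the index of the tested column.

    Without an environment each test is the single marker column (q = 1).
    With an environment each block is [marker, marker*env] (q = 2) and the
    Wald contrast selects only the interaction column.
    """
    X = np.asarray(dosages, dtype=float)
    if standardize:
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    if env is None:
        return X.T[:, :, None], 0
    env = np.asarray(env, dtype=float)
    if np.all(env == env[0]):
        raise ValueError("environment vector is constant")
    blocks = np.stack([X.T, X.T * env[None, :]], axis=2)
    return blocks, 1


def build_gxe_design(spec: ModelSpec, marker: np.ndarray, env: np.ndarray) -> tuple[ModelSpec, np.ndarray]:
    """Single-marker G-by-E model: env main effect in W, X = [marker, marker*env].

    Returns the augmented spec and the Wald contrast selecting only the
    interaction coefficient (q = 1).
    """
    env = np.asarray(env, dtype=float)
    if np.all(env == env[0]):
        raise ValueError("environment vector is constant")
    marker = np.asarray(marker, dtype=float).ravel()
    W = np.column_stack([spec.W, env])
    X = np.column_stack([marker, marker * env])
    out = ModelSpec(spec.y, W, X, spec.random_effects)
    M = np.zeros((1, W.shape[1] + 2))
    M[0, -1] = 1.0
    return out, M


def _null_ml_max(spec: ModelSpec, m0: int = 10, refinements: int = 2) -> float:
    """ML profile maximum of the covariate-only model by grid refinement."""
    ev = VertexEvaluator(spec.without_markers(), criterion="ML")
    cache: dict = {}

    def score(v):
        k = v.h2
        if k not in cache:
            cache[k] = float(ev.scores(v)[0])
        return cache[k]

    grid = build_grid(spec.L, m0)
    best = max(grid.vertices, key=score)
    m = m0
    for _ in range(refinements + 1):
        while True:
            nb = fast_search.ball_vertices(best, m, include_center=False)
            cand = max(nb, key=score, default=None)
            if cand is None or score(cand) <= score(best):
                break
            best = cand
        m *= 2
    return score(best)


def _bayes_ring_scan(
    ev: VertexEvaluator,
    grid: GridSpec,
    h0: GridVertex,
    stop_fraction: float,
) -> tuple[GridScores, np.ndarray, fast_search.SearchTrace]:
    """Vectorized concentric-ring evaluation of marginal likelihoods.

    Rings expand outward from the pegged center until every marker's last
    ring contributed less than ``stop_fraction`` of its accumulated
    posterior mass (or the grid is exhausted).
    """
    from scipy.special import logsumexp

    arr = grid.as_array()[:, : grid.L]
    center = np.array(h0.h2)
    dist = np.rint(np.max(np.abs(arr - center), axis=1) * grid.m).astype(int)
    g, p = grid.g, ev.n_tests
    alt = np.full((p, g), np.nan)
    null = np.full(g, np.nan)
    trace = fast_search.SearchTrace()
    running = np.full(p, -np.inf)  # per-marker logsumexp of evaluated mass
    max_ring = int(dist.max())
    for r in range(max_ring + 1):
        idx = np.where(dist == r)[0]
        if idx.size == 0:
            continue
        for j in idx:
            v = grid.vertices[j]
            alt[:, j] = ev.scores(v)
            null[j] = ev.null_marginal(v)
            trace.evaluated.append(v)
        with np.errstate(invalid="ignore"):
            ring_mass = logsumexp(np.nan_to_num(alt[:, idx], nan=-np.inf), axis=1)
            new_total = np.logaddexp(running, ring_mass)
            frac = np.exp(ring_mass - new_total)
        running = new_total
        trace.log(ring=r, vertices=int(idx.size), max_fraction=float(np.nanmax(frac)))
        if r >= 1 and np.all(frac < stop_fraction):
            break
    else:
        trace.flags.append("grid_exhausted")
    scores = GridScores([f"t{i}" for i in range(p)], list(grid.vertices), alt, "marginal")
    return scores, null, trace


def run_association_scan(
    spec: ModelSpec,
    markers,
    config: ScanConfig | None = None,
    env: np.ndarray | None = None,
) -> AssociationTable:
    """Scan every marker for association, one result row per marker.

    ``env`` (a ±1 vector) switches the scan to interaction tests: the
    environment main effect joins the covariates and each marker is tested
    only through its marker-by-environment column.  Markers failing
    variance or rank checks are NA-flagged, never dropped silently.
    """
    config = config or ScanConfig()
    dosages, labels, chrom, pos = _marker_array(markers)
    n, p_all = dosages.shape
    if n != spec.n:
        raise ValueError("marker rows do not match model observations")
    if env is not None:
        env = np.asarray(env, dtype=float)
        spec = ModelSpec(spec.y, np.column_stack([spec.W, env]), None, spec.random_effects)
    usable = dosages.std(axis=0) > 0
    if env is not None:
        usable &= (dosages * env[:, None]).std(axis=0) > 0
    if not usable.any():
        if p_all == 0:
            return AssociationTable(_empty_frame(spec.L), config)
        raise ValueError("no usable (polymorphic) markers")
    blocks, contrast_col = build_marker_blocks(
        dosages[:, usable], env, standardize=config.standardize
    )
    criterion = {"wald": "REML", "lrt": "ML", "bayes": "marginal"}[config.method]
    ev = VertexEvaluator(
        spec, marker_blocks=blocks, criterion=criterion, psi_marker=config.psi_marker
    )

    h0 = None
    if config.search in ("fast", "null") or config.peg == "null":
        h0 = fast_search.null_reml_estimate(spec)

    trace = None
    null_marginals = None
    if config.search == "null":
        scores = GridScores(
            [f"t{i}" for i in range(ev.n_tests)], [h0], ev.scores(h0)[:, None], criterion
        )
        if config.method == "bayes":
            null_marginals = np.array([ev.null_marginal(h0)])
    elif config.method == "bayes":
        grid = build_grid(spec.L, config.m, peg=h0 if config.peg == "null" else None)
        if config.search == "fast":
            scores, null_marginals, trace = _bayes_ring_scan(
                ev, grid, h0 if h0 is not None else GridVertex((0.0,) * spec.L),
                config.ring_stop_fraction,
            )
        else:
            scores = grid_search(spec, grid, evaluator=ev, max_cells=config.max_cells)
            null_marginals = np.array([ev.null_marginal(v) for v in grid.vertices])
    elif config.search == "full":
        grid = build_grid(spec.L, config.m, peg=h0 if config.peg == "null" else None)
        scores = grid_search(spec, grid, evaluator=ev, max_cells=config.max_cells)
    else:  # fast
        scores, trace = fast_search.reml_ball_search(
            spec, blocks, m=config.m, h0=h0, evaluator=ev,
            settings=fast_search.SearchSettings(m=config.m),
        )

    frame = _assemble_table(
        spec, ev, scores, null_marginals, config, contrast_col,
        usable, labels, chrom, pos,
    )
    gc = None
    if config.method == "wald" and config.genomic_control:
        F = frame["F"].to_numpy()
        if np.isfinite(F).any():
            gc = genomic_control(F[np.isfinite(F)], 1, spec.n - spec.c - ev.q)
    return AssociationTable(frame, config, h0=h0, gc=gc, trace=trace)


def _empty_frame(L: int) -> pd.DataFrame:
    cols = list(TABLE_COLUMNS) + [f"h2_{l + 1}" for l in range(L)] + [
        "h2_e", "logscore", "log10BF", "flag",
    ]
    return pd.DataFrame({c: [] for c in cols})


def _assemble_table(
    spec, ev, scores: GridScores, null_marginals, config, contrast_col,
    usable, labels, chrom, pos,
) -> pd.DataFrame:
    L = spec.L
    p_all = usable.shape[0]
    frame = _empty_frame(L)
    out = {c: np.full(p_all, np.nan) for c in frame.columns if c not in ("marker", "flag")}
    flags = np.where(usable, "", "monomorphic").astype(object)
    sub = np.where(usable)[0]

    best_idx = scores.best_idx
    evaluated = ~np.all(np.isnan(scores.scores), axis=1)
    q = ev.q

    if config.method in ("wald", "lrt"):
        groups: dict[int, list[int]] = {}
        for t in range(len(sub)):
            if best_idx[t] >= 0 and np.isfinite(scores.best_score[t]):
                groups.setdefault(int(best_idx[t]), []).append(t)
            else:
                flags[sub[t]] = "rank_deficient"
        if config.method == "lrt":
            ml_null = _null_ml_max(spec)
        for vi, tests in groups.items():
            vertex = scores.vertices[vi]
            idx = np.array(tests)
            beta, se, F, df2 = ev.wald_stats(vertex, idx, contrast_col=contrast_col)
            rows = sub[idx]
            out["beta"][rows] = beta
            out["se"][rows] = se
            arr = list(vertex.h2)
            for l in range(L):
                out[f"h2_{l + 1}"][rows] = arr[l]
            out["h2_e"][rows] = vertex.he2
            out["logscore"][rows] = scores.best_score[idx]
            if config.method == "wald":
                out["F"][rows] = F
                out["df1"][rows] = 1
                out["df2"][rows] = df2
                out["p"][rows] = stats.f.sf(F, 1, df2)
            else:
                lr = np.maximum(2.0 * (scores.best_score[idx] - ml_null), 0.0)
                out["F"][rows] = lr
                out["df1"][rows] = q
                out["df2"][rows] = 0
                out["p"][rows] = stats.chi2.sf(lr, q)
    else:  # bayes
        from .bayes_engine import bayes_factor

        bf = bayes_factor(scores, null_marginals)
        log10bf = bf.log10_BF
        for t in range(len(sub)):
            row = sub[t]
            if not evaluated[t] or not np.isfinite(scores.best_score[t]):
                flags[row] = "rank_deficient"
                continue
            out["log10BF"][row] = log10bf[t]
            vertex = scores.vertices[int(best_idx[t])]
            for l in range(L):
                out[f"h2_{l + 1}"][row] = vertex.h2[l]
            out["h2_e"][row] = vertex.he2
            out["logscore"][row] = scores.best_score[t]

    data = {"marker": labels}
    data["chrom"] = chrom if chrom is not None else np.full(p_all, np.nan)
    data["pos"] = pos if pos is not None else np.full(p_all, np.nan)
    for c in frame.columns:
        if c in ("marker", "chrom", "pos", "flag"):
            continue
        data[c] = out[c]
    data["flag"] = flags
    return pd.DataFrame(data)


def genomic_control(F_stats: np.ndarray, df1: int, df2: int) -> GCResult:
    """Inflation factor: median observed F over the null F-distribution median.

    The corrected statistics (F / lambda) are returned for reporting;
    stored p-values are never silently rescaled.
    """
    F = np.asarray(F_stats, dtype=float)
    finite = np.isfinite(F)
    if not finite.any():
        raise ValueError("no finite statistics for genomic control")
    lam = float(np.median(F[finite]) / stats.f.ppf(0.5, df1, df2))
    return GCResult(lam, df1, df2, F / lam)


@dataclass
class VCScanResult:
    """Per-trait variance-component estimates and grid posteriors."""

    frame: pd.DataFrame
    grid: GridSpec
    posteriors: list  # PosteriorGrid or None per trait


def variance_component_scan(
    traits: np.ndarray,
    spec: ModelSpec,
    m: int = 20,
    compute_posterior: bool = True,
    trait_labels: list[str] | None = None,
) -> VCScanResult:
    """REML point estimates and grid posteriors of h2 for many traits.

    Reuses one rotation per vertex across all traits.  Constant traits are
    NA-flagged.  The posterior uses a uniform prior over the grid; the
    probability of a non-zero component is the mass off its zero face.
    """
    traits = np.asarray(traits, dtype=float)
    if traits.ndim == 1:
        traits = traits[:, None]
    n, T = traits.shape
    if n != spec.n:
        raise ValueError("trait rows do not match model observations")
    L = spec.L
    grid = build_grid(L, m)
    if trait_labels is None:
        trait_labels = [f"trait{t}" for t in range(T)]
    cols: dict = {"trait": trait_labels}
    for l in range(L):
        cols[f"h2_{l + 1}_reml"] = np.full(T, np.nan)
    cols["h2_e_reml"] = np.full(T, np.nan)
    for l in range(L):
        cols[f"h2_{l + 1}_postmean"] = np.full(T, np.nan)
    cols["h2_e_postmean"] = np.full(T, np.nan)
    for l in range(L):
        cols[f"p_nonzero_{l + 1}"] = np.full(T, np.nan)
    cols["flag"] = np.array([""] * T, dtype=object)
    posteriors: list = [None] * T
    if T == 0:
        return VCScanResult(pd.DataFrame(cols), grid, posteriors)

    ok = traits.std(axis=0) > 0
    for t in np.where(~ok)[0]:
        cols["flag"][t] = "constant_trait"
    if ok.any():
        sub = traits[:, ok]
        base = spec.without_markers()
        reml_scores = grid_search(base, grid, markers=sub, tests="per-trait", criterion="REML")
        arr = grid.as_array()
        for j, t in enumerate(np.where(ok)[0]):
            vi = int(reml_scores.best_idx[j])
            for l in range(L):
                cols[f"h2_{l + 1}_reml"][t] = arr[vi, l]
            cols["h2_e_reml"][t] = arr[vi, -1]
        if compute_posterior:
            marg = grid_search(base, grid, markers=sub, tests="per-trait", criterion="marginal")
            for j, t in enumerate(np.where(ok)[0]):
                post = grid_posterior(grid, marg.scores[j])
                posteriors[t] = post
                for l in range(L):
                    cols[f"h2_{l + 1}_postmean"][t] = post.posterior_mean_h2[l]
                cols["h2_e_postmean"][t] = post.posterior_mean_h2[-1]
                pnz = post.component_nonzero_prob()
                for l in range(L):
                    cols[f"p_nonzero_{l + 1}"][t] = pnz[l]
    return VCScanResult(pd.DataFrame(cols), grid, posteriors)
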