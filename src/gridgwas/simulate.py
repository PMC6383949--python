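"""Synthetic structured populations and multi-random-effect phenotypes.

Generates family-block genotype matrices (Balding–Nichols-style allele
frequency differentiation between blocks), phenotypes composed of a
single causal-marker effect, correlated random-effect draws with given
variance proportions, and iid noise scaled so the theoretical total
variance is one; plus the block-diagonal population expansion and the
worst-case vertex perturbation used for approximation-accuracy studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .kinships import GenotypeMatrix, RelationshipMatrix
from .lmm_core import GridVertex

__all__ = [
    "SimSpec",
    "SimDataset",
    "simulate_structured_genotypes",
    "simulate_phenotype",
    "expand_population",
    "subsample_population",
    "perturb_vertex",
]


@dataclass
class SimSpec:
    n: int
    p: int
    blocks: int = 1
    fst: float = 0.3  # between-block differentiation
    proportions: tuple[float, ...] = ()
    causal_index: int | None = None
    effect_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.proportions):
            raise ValueError("variance proportions must be non-negative")
        if sum(self.proportions) + self.effect_fraction > 1.0 + 1e-12:
            raise ValueError("proportions plus effect fraction exceed total variance")
        if not (0.0 <= self.effect_fraction <= 0.2):
            raise ValueError("effect fraction outside supported range [0, 0.2]")


@dataclass
class SimDataset:
    genotypes: GenotypeMatrix
    kinships: list[RelationshipMatrix]
    phenotype: np.ndarray
    truth: dict = field(default_factory=dict)


def simulate_structured_genotypes(
    n: int,
    p: int,
    blocks: int = 1,
    fst: float = 0.3,
    seed: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Family-block dosage matrix with elevated within-block relatedness.

    Ancestral allele frequencies are uniform on (0.1, 0.9); each block
    draws its own frequency from a Beta with the Balding–Nichols
    variance parameter ``fst``; dosages are Binomial(2, block frequency).
    """
    if n < 1 or p < 1:
        raise ValueError("n and p must be >= 1")
    if blocks > n:
        raise ValueError(f"more blocks ({blocks}) than samples ({n})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    anc = rng.uniform(0.1, 0.9, size=p)
    block_of = np.repeat(np.arange(blocks), -(-n // blocks))[:n]
    if fst > 0:
        ratio = (1.0 - fst) / fst
        freq = rng.beta(anc * ratio, (1.0 - anc) * ratio, size=(blocks, p))
    else:
        freq = np.tile(anc, (blocks, 1))
    dosages = rng.binomial(2, freq[block_of, :]).astype(float)
    samples = [f"s{i}" for i in range(n)]
    markers = [f"m{j}" for j in range(p)]
    G = GenotypeMatrix(samples, markers, dosages)
    G.block_of = block_of  # family labels, handy for grouping random effects
    return G


def _correlated_draw(
    K: RelationshipMatrix, rng: np.random.Generator, jitter: float = 1e-8
) -> tuple[np.ndarray, float]:
    """Draw N(0, K) via the kinship Cholesky, jittering if not PD."""
    z = rng.standard_normal(K.n)
    used = 0.0
    try:
        C = sla.cholesky(K.values, lower=True)
    except sla.LinAlgError:
        used = jitter * np.trace(K.values) / K.n
        try:
            C = sla.cholesky(K.values + used * np.eye(K.n), lower=True)
        except sla.LinAlgError as exc:
            raise ValueError("kinship is not positive semi-definite") from exc
    return C @ z, used


def simulate_phenotype(
    kinships: list[RelationshipMatrix],
    proportions: tuple[float, ...],
    marker: np.ndarray | None = None,
    effect_fraction: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, dict]:
    """Phenotype = marker effect + correlated random draws + iid noise.

    ``proportions[l]`` is the variance weight of ``kinships[l]``; the
    residual receives ``1 - sum(proportions) - effect_fraction`` so the
    theoretical total variance is one.  The marker column is standardized
    before scaling, so ``effect_fraction`` is its realized variance share
    in expectation.  Returns the phenotype and a truth record sufficient
    to regenerate it bit-exactly.
    """
    if len(proportions) != len(kinships):
        raise ValueError("one proportion per kinship required")
    resid = 1.0 - sum(proportions) - effect_fraction
    if resid < -1e-12:
        raise ValueError("variance proportions exceed one")
    resid = max(resid, 0.0)
    rng_seed = seed if not isinstance(seed, np.random.Generator) else None
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = kinships[0].n if kinships else (len(marker) if marker is not None else 0)
    y = np.zeros(n)
    jitters = []
    for w, K in zip(proportions, kinships):
        g, jit = _correlated_draw(K, rng)
        jitters.append(jit)
        if w > 0:
            y = y + np.sqrt(w) * g
    if effect_fraction > 0:
        if marker is None:
            raise ValueError("effect_fraction > 0 requires a marker column")
        x = np.asarray(marker, dtype=float)
        sd = x.std()
        if sd == 0:
            raise ValueError("causal marker is monomorphic")
        y = y + np.sqrt(effect_fraction) * (x - x.mean()) / sd
    y = y + np.sqrt(resid) * rng.standard_normal(n)
    truth = {
        "proportions": tuple(proportions),
        "effect_fraction": float(effect_fraction),
        "residual": float(resid),
        "seed": rng_seed,
        "jitters": jitters,
    }
    return y, truth


def expand_population(
    kinships: list[RelationshipMatrix],
    genotypes: GenotypeMatrix,
    factor: int,
) -> tuple[list[RelationshipMatrix], GenotypeMatrix]:
    """Replicate the population ``factor`` times.

    Marker rows are tiled and each kinship becomes block-diagonal with
    ``factor`` copies, so copies of different blocks are exactly unrelated
    and the expanded spectrum is the original one repeated.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return list(kinships), genotypes
    n = genotypes.n
    samples = [f"{s}_r{r}" for r in range(factor) for s in genotypes.samples]
    G = GenotypeMatrix(
        samples, list(genotypes.markers), np.tile(genotypes.dosages, (factor, 1))
    )
    out = []
    for K in kinships:
        big = np.kron(np.eye(factor), K.values)
        out.append(RelationshipMatrix(samples, big, normalized=K.normalized))
    return out, G


def subsample_population(
    kinships: list[RelationshipMatrix],
    genotypes: GenotypeMatrix,
    count: int,
) -> tuple[list[RelationshipMatrix], GenotypeMatrix]:
    """Leading-row subsample of genotypes and matching kinship sub-blocks."""
    if not (1 <= count <= genotypes.n):
        raise ValueError("count must be between 1 and n")
    samples = genotypes.samples[:count]
    G = GenotypeMatrix(samples, list(genotypes.markers), genotypes.dosages[:count])
    out = [
        RelationshipMatrix(list(samples), K.values[:count, :count], normalized=K.normalized)
        for K in kinships
    ]
    return out, G


def perturb_vertex(vertex: GridVertex, delta: float) -> list[GridVertex]:
    """The 2^L sign-combination neighbors of a vertex, clipped to the simplex.

    Used for worst-case approximation studies: score each neighbor and
    keep the test statistic from the best-scoring one, as if the true
    optimum sat exactly between grid vertices.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    out = []
    import itertools

    for signs in itertools.product((-1.0, 1.0), repeat=vertex.L):
        coords = tuple(c + s * delta for c, s in zip(vertex.h2, signs))
        if any(v < -1e-12 for v in coords):
            continue
        coords = tuple(max(v, 0.0) for v in coords)
        if sum(coords) >= 1.0 - 1e-9:
            continue
        out.append(GridVertex(coords))
    return out
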