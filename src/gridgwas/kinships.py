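"""Relationship-matrix construction and normalization.

Builds the covariance structures used as random-effect kernels: the
genome-wide additive relationship matrix (VanRaden method 1), the
pairwise-epistatic kernel (Hadamard square of the additive kernel), the
signed gene-by-environment kernel ``D Z K Z^T D``, and categorical
(grouping) kernels.  All kernels are validated as symmetric and positive
semi-definite and can be normalized to mean diagonal one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "RelationshipMatrix",
    "IncidenceMap",
    "additive_kinship",
    "epistatic_kinship",
    "gxe_kinship",
    "normalize_kinship",
]

SYMMETRY_TOL = 1e-10
# smallest eigenvalue may undershoot zero by this fraction of trace/n
PSD_TOL = 1e-8


class KinshipError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Sample-by-marker dosage matrix with allele counts in [0, 2].

    Missing dosages must be imputed (per-marker mean) before
    construction; :meth:`from_dosages` performs this.
    """

    samples: list[str]
    markers: list[str]
    dosages: np.ndarray  # (n, p) float
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    polymorphic: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise KinshipError("dosages must be a 2-D (samples x markers) array")
        n, p = self.dosages.shape
        if len(self.samples) != n or len(self.markers) != p:
            raise KinshipError("label lengths do not match dosage dimensions")
        if np.isnan(self.dosages).any():
            raise KinshipError("missing dosages; impute before construction")
        self.polymorphic = self.dosages.std(axis=0) > 0

    @classmethod
    def from_dosages(
        cls,
        dosages: np.ndarray,
        samples: Sequence[str] | None = None,
        markers: Sequence[str] | None = None,
        **kw,
    ) -> "GenotypeMatrix":
        """Build from a raw dosage array, mean-imputing NaNs per marker."""
        dosages = np.array(dosages, dtype=float)
        if np.isnan(dosages).any():
            col_mean = np.nanmean(dosages, axis=0)
            idx = np.where(np.isnan(dosages))
            dosages[idx] = np.take(col_mean, idx[1])
        n, p = dosages.shape
        if samples is None:
            samples = [f"s{i}" for i in range(n)]
        if markers is None:
            markers = [f"m{j}" for j in range(p)]
        return cls(list(samples), list(markers), dosages, **kw)

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def p(self) -> int:
        return self.dosages.shape[1]


def _check_psd(values: np.ndarray, n: int) -> None:
    w = np.linalg.eigvalsh(values)
    tol = PSD_TOL * max(np.trace(values) / n, 1.0)
    if w[0] < -tol:
        raise KinshipError(
            f"matrix is not positive semi-definite (min eigenvalue {w[0]:.3e})"
        )


@dataclass
class RelationshipMatrix:
    """Symmetric PSD covariance kernel over a set of samples."""

    samples: list[str]
    values: np.ndarray  # (n, n)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise KinshipError("kinship shape does not match sample labels")
        if not np.allclose(self.values, self.values.T, atol=SYMMETRY_TOL):
            raise KinshipError("kinship matrix is not symmetric")
        # exact symmetry simplifies downstream Cholesky calls
        self.values = (self.values + self.values.T) / 2.0

    def validate_psd(self) -> "RelationshipMatrix":
        _check_psd(self.values, len(self.samples))
        return self

    @property
    def n(self) -> int:
        return len(self.samples)


@dataclass
class IncidenceMap:
    """Observation-to-level assignment with optional ±1 environment signs."""

    assignments: list[str]  # length n, one level label per observation
    levels: list[str]
    signs: np.ndarray | None = None  # length n of ±1 (diagonal of D)

    def __post_init__(self) -> None:
        level_index = {lab: i for i, lab in enumerate(self.levels)}
        if len(level_index) != len(self.levels):
            raise KinshipError("duplicate level labels")
        missing = [a for a in self.assignments if a not in level_index]
        if missing:
            raise KinshipError(f"unmapped observation labels: {missing[:5]}")
        self._codes = np.array([level_index[a] for a in self.assignments])
        if self.signs is not None:
            self.signs = np.asarray(self.signs, dtype=float)
            if self.signs.shape != (len(self.assignments),):
                raise KinshipError("signs must have one entry per observation")
            if not np.all(np.isin(self.signs, (-1.0, 1.0))):
                raise KinshipError("signs must be -1 or +1")

    @property
    def n(self) -> int:
        return len(self.assignments)

    @property
    def r(self) -> int:
        return len(self.levels)

    def matrix(self) -> np.ndarray:
        """Dense 0/1 incidence matrix Z of shape (n, r)."""
        Z = np.zeros((self.n, self.r))
        Z[np.arange(self.n), self._codes] = 1.0
        return Z

    @classmethod
    def from_labels(cls, labels: Sequence[str], signs=None) -> "IncidenceMap":
        levels = list(dict.fromkeys(labels))
        return cls(list(labels), levels, signs)


def additive_kinship(G: GenotypeMatrix, center: bool = True) -> RelationshipMatrix:
    """Genome-wide additive relationship matrix, VanRaden method 1.

    K = (G - 2f)(G - 2f)^T / (2 * sum_j f_j (1 - f_j)) over polymorphic
    markers, optionally centered (intercept projected out) and always
    normalized to mean diagonal one.
    """
    poly = G.polymorphic
    if not poly.any():
        raise KinshipError("all markers are monomorphic; cannot build kinship")
    dos = G.dosages[:, poly]
    f = dos.mean(axis=0) / 2.0
    Wc = dos - 2.0 * f
    denom = 2.0 * np.sum(f * (1.0 - f))
    K = (Wc @ Wc.T) / denom
    rel = RelationshipMatrix(G.samples, K)
    return normalize_kinship(rel, center=center)


def epistatic_kinship(
    K: RelationshipMatrix, renormalize: bool = True
) -> RelationshipMatrix:
    """Pairwise-epistatic kernel: element-wise square of K.

    The Hadamard square of a PSD matrix is PSD (Schur product theorem).
    Renormalization to mean diagonal one is on by default.
    """
    out = RelationshipMatrix(K.samples, K.values * K.values)
    if renormalize:
        out = normalize_kinship(out, center=False)
    return out


def gxe_kinship(K: RelationshipMatrix, Z: IncidenceMap) -> RelationshipMatrix:
    """Signed expanded kernel D Z K Z^T D.

    With all signs +1 this is the expanded kinship Z K Z^T; with K = I it
    degenerates to the categorical (iid level) covariance.
    """
    if Z.r != K.n:
        raise KinshipError(
            f"incidence map has {Z.r} levels but kinship has {K.n} samples"
        )
    if Z.signs is None:
        raise KinshipError("gxe_kinship requires environment signs on the incidence map")
    expanded = K.values[np.ix_(Z._codes, Z._codes)]
    d = Z.signs
    values = expanded * np.outer(d, d)
    return RelationshipMatrix(list(Z.assignments), values)


def expand_kinship(K: RelationshipMatrix, Z: IncidenceMap) -> RelationshipMatrix:
    """Unsigned expansion Z K Z^T to observation level."""
    if Z.r != K.n:
        raise KinshipError(
            f"incidence map has {Z.r} levels but kinship has {K.n} samples"
        )
    expanded = K.values[np.ix_(Z._codes, Z._codes)]
    return RelationshipMatrix(list(Z.assignments), expanded)


def categorical_kinship(Z: IncidenceMap) -> RelationshipMatrix:
    """iid level covariance Z Z^T (block matrix of ones per level)."""
    eye = RelationshipMatrix(list(Z.levels), np.eye(Z.r))
    return expand_kinship(eye, Z)


def normalize_kinship(K: RelationshipMatrix, center: bool = False) -> RelationshipMatrix:
    """Center (project out the intercept) and/or scale to mean diagonal one."""
    values = K.values
    n = K.n
    if center:
        row_mean = values.mean(axis=0, keepdims=True)
        values = values - row_mean - row_mean.T + values.mean()
    tr = np.trace(values)
    if tr <= 0:
        raise KinshipError("zero-trace kinship cannot be normalized")
    values = values * (n / tr)
    return RelationshipMatrix(K.samples, values, normalized=True)
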