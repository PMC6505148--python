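"""Deterministic matrix kernels shared by all models.

Provides the genomic relationship matrix (GRM) of VanRaden form
``G = W W' / p``, a PSD-safe Cholesky factorization used to whiten design
matrices, covariance-to-correlation conversion, and the Kronecker product
used to build the genotype-by-environment covariance ``I_I (x) G``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataValidationError, NumericalError

__all__ = [
    "MarkerMatrix",
    "GenomicRelationship",
    "grm_vanraden",
    "safe_cholesky",
    "cov_to_correlation",
    "kronecker_product",
]


@dataclass
class MarkerMatrix:
    """Lines-by-markers dosage matrix; ``nan`` marks missing calls."""

    values: np.ndarray
    line_ids: list = field(default_factory=list)
    marker_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataValidationError("marker matrix must be two-dimensional")
        j, p = self.values.shape
        if not self.line_ids:
            self.line_ids = [f"L{i + 1}" for i in range(j)]
        if not self.marker_ids:
            self.marker_ids = [f"M{i + 1}" for i in range(p)]
        if len(self.line_ids) != j:
            raise DataValidationError(
                f"{len(self.line_ids)} line ids for {j} marker-matrix rows"
            )
        if len(self.marker_ids) != p:
            raise DataValidationError(
                f"{len(self.marker_ids)} marker ids for {p} marker-matrix columns"
            )

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.line_ids, columns=self.marker_ids).to_csv(path)

    @classmethod
    def read_csv(cls, path) -> "MarkerMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), list(df.index.astype(str)), list(df.columns))


@dataclass
class GenomicRelationship:
    """J x J genomic relationship matrix among lines (symmetric, PSD)."""

    values: np.ndarray
    line_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise DataValidationError("GRM must be square")
        j = self.values.shape[0]
        if not self.line_ids:
            self.line_ids = [f"L{i + 1}" for i in range(j)]
        if len(self.line_ids) != j:
            raise DataValidationError(f"{len(self.line_ids)} line ids for {j}x{j} GRM")
        scale = max(np.abs(self.values).max(), 1.0)
        if np.abs(self.values - self.values.T).max() > 1e-10 * scale:
            raise DataValidationError("GRM is not symmetric within tolerance")
        ev = np.linalg.eigvalsh(self.values)
        if ev[0] < -1e-8 * max(ev[-1], 0.0) - 1e-12:
            raise DataValidationError(
                f"GRM is not positive semidefinite (min eigenvalue {ev[0]:.3e})"
            )

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    def reindex(self, line_ids) -> "GenomicRelationship":
        """Sub-GRM in the given line order; errors list any absent lines."""
        pos = {g: i for i, g in enumerate(self.line_ids)}
        missing = [g for g in line_ids if g not in pos]
        if missing:
            raise DataValidationError(
                "lines absent from the GRM: " + ", ".join(str(g) for g in missing)
            )
        idx = np.array([pos[g] for g in line_ids])
        return GenomicRelationship(self.values[np.ix_(idx, idx)], list(line_ids))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.line_ids, columns=self.line_ids).to_csv(path)

    @classmethod
    def read_csv(cls, path) -> "GenomicRelationship":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), list(df.index.astype(str)))


def grm_vanraden(W: MarkerMatrix) -> GenomicRelationship:
    """Genomic relationship matrix ``G = W W' / p`` from a QC'd marker matrix.

    No centering or scaling is applied to ``W``; callers that want a centered
    GRM must center beforehand.
    """
    vals = W.values
    if vals.shape[1] == 0:
        raise DataValidationError("marker matrix has zero markers (p = 0)")
    miss = np.argwhere(np.isnan(vals))
    if miss.size:
        r, c = miss[0]
        raise DataValidationError(
            f"missing marker entries present; first at line {W.line_ids[r]!r}, "
            f"marker {W.marker_ids[c]!r} — run marker QC/imputation first"
        )
    p = vals.shape[1]
    return GenomicRelationship(vals @ vals.T / p, list(W.line_ids))


def safe_cholesky(M: np.ndarray, *, sym_tol: float = 1e-8) -> np.ndarray:
    """Lower Cholesky factor of a symmetric PSD matrix.

    Positive-definite input uses the standard factorization.  Semidefinite or
    numerically indefinite input is repaired by clipping eigenvalues below
    ``1e-10 * max eigenvalue`` up to that threshold and factorizing the
    reconstruction, so rank-deficient GRMs (few markers) always factor.
    The returned factor has a non-negative diagonal and satisfies
    ``L @ L.T ~= clipped M``.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise DataValidationError("safe_cholesky requires a square matrix")
    scale = max(np.abs(M).max(), 1.0)
    if np.abs(M - M.T).max() > sym_tol * scale:
        raise DataValidationError("safe_cholesky requires a symmetric matrix")
    Ms = 0.5 * (M + M.T)
    try:
        return np.linalg.cholesky(Ms)
    except np.linalg.LinAlgError:
        pass
    w, V = np.linalg.eigh(Ms)
    lam_max = w[-1]
    if lam_max <= 0.0:
        # zero (or negative-noise) matrix: the zero factor reconstructs it
        return np.zeros_like(Ms)
    eps = 1e-10 * lam_max
    w = np.clip(w, eps, None)
    rebuilt = (V * w) @ V.T
    rebuilt = 0.5 * (rebuilt + rebuilt.T)
    try:
        return np.linalg.cholesky(rebuilt)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - clip guarantees PD
        raise NumericalError("Cholesky failed after eigenvalue clipping") from exc


def cov_to_correlation(S: np.ndarray) -> np.ndarray:
    """Convert a covariance matrix to a correlation matrix.

    ``R[i, j] = S[i, j] / sqrt(S[i, i] * S[j, j])`` with a unit diagonal.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise DataValidationError("covariance matrix must be square")
    d = np.diag(S)
    bad = np.flatnonzero(d <= 0)
    if bad.size:
        raise DataValidationError(
            f"non-positive variance for trait index {int(bad[0])}; cannot form correlations"
        )
    s = np.sqrt(d)
    R = S / np.outer(s, s)
    R = 0.5 * (R + R.T)
    np.fill_diagonal(R, 1.0)
    return R


def kronecker_product(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Kronecker product ``A (x) B`` with the usual block layout A[i,j]*B."""
    return np.kron(np.asarray(A, dtype=float), np.asarray(B, dtype=float))
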