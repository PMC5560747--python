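"""Drug-side kernels: Tanimoto fingerprint kernels and the Gaussian
interaction-profile (GIP) kernel.

A fingerprint kernel is built in two steps: a Tanimoto similarity matrix
S_D over all compound pairs, then the linear kernel K_D = S_D S_D^T followed
by cosine normalization so that the diagonal is exactly one.  The GIP kernel
is a Gaussian kernel on interaction profiles -- a compound's vector of
(imputed) binding affinities across the protein panel.  The same two
primitives serve the protein side (see :mod:`kronaff.protein_kernels`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, cdist, squareform

from .io_formats import FingerprintSet

__all__ = [
    "KernelMatrix",
    "SimilarityMatrix",
    "tanimoto_similarity",
    "tanimoto_similarity_matrix",
    "cosine_normalize",
    "linear_kernel_from_similarity",
    "gip_kernel",
    "sigma_grid_from_distances",
]

SYMMETRY_TOL = 1e-10
PSD_FLOOR = 1e-8


@dataclass
class KernelMatrix:
    """Square symmetric positive-semidefinite similarity kernel.

    ``normalized`` records whether cosine normalization was applied (unit
    diagonal).  Validation enforces symmetry to 1e-10 and eigenvalues above
    ``-1e-8 * lambda_max``.
    """

    ids: list[str]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("kernel must be square over its ids")
        self.check()

    def check(self) -> None:
        if not np.all(np.abs(self.values - self.values.T) <= SYMMETRY_TOL):
            raise ValueError("kernel matrix is not symmetric")
        eigvals = np.linalg.eigvalsh(self.values)
        lam_max = max(eigvals[-1], 0.0)
        if eigvals[0] < -PSD_FLOOR * max(lam_max, 1.0):
            raise ValueError(
                f"kernel matrix is not PSD: min eigenvalue {eigvals[0]:.3e}"
            )
        if self.normalized and not np.all(
            np.abs(np.diag(self.values) - 1.0) <= SYMMETRY_TOL
        ):
            raise ValueError("normalized kernel must have unit diagonal")

    def submatrix(self, indices: Sequence[int]) -> "KernelMatrix":
        idx = np.asarray(indices)
        return KernelMatrix(
            [self.ids[i] for i in idx],
            self.values[np.ix_(idx, idx)],
            normalized=self.normalized,
        )


@dataclass
class SimilarityMatrix:
    """Labeled real similarity matrix; rectangular allowed (feature profiles)."""

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("similarity matrix shape does not match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("similarity matrix must be finite")

    @property
    def is_square(self) -> bool:
        return self.row_ids == self.col_ids


def tanimoto_similarity(fp_i: np.ndarray, fp_j: np.ndarray) -> float:
    """Tanimoto (Jaccard) similarity of two binary fingerprints.

    N11 / (N_i + N_j - N11) with N11 the shared on-bits.  Two all-zero
    fingerprints score 1 (identical objects); one empty against a non-empty
    fingerprint scores 0.
    """
    a = np.asarray(fp_i)
    b = np.asarray(fp_j)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    n11 = int(np.sum((a == 1) & (b == 1)))
    ni, nj = int(a.sum()), int(b.sum())
    denom = ni + nj - n11
    if denom == 0:
        return 1.0
    return n11 / denom


def tanimoto_similarity_matrix(fps: FingerprintSet) -> SimilarityMatrix:
    """All-pairs Tanimoto scores S_D over a fingerprint set."""
    bits = fps.bits.astype(float)
    inner = bits @ bits.T
    counts = bits.sum(axis=1)
    denom = counts[:, None] + counts[None, :] - inner
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, inner / np.where(denom > 0, denom, 1.0), 1.0)
    return SimilarityMatrix(list(fps.drug_ids), list(fps.drug_ids), sim)


def cosine_normalize(values: np.ndarray) -> np.ndarray:
    """K'(i,j) = K(i,j) / sqrt(K(i,i) K(j,j)); zero-diagonal rows map to a
    unit self-similarity with zero off-diagonal entries."""
    diag = np.diag(values).copy()
    zero = diag <= 0
    scale = np.where(zero, 1.0, np.sqrt(np.where(zero, 1.0, diag)))
    out = values / np.outer(scale, scale)
    if zero.any():
        out[zero, :] = 0.0
        out[:, zero] = 0.0
        out[np.ix_(zero, zero)] = 0.0
    np.fill_diagonal(out, 1.0)
    return out


def _psd_repair(values: np.ndarray) -> np.ndarray:
    eigvals, eigvecs = np.linalg.eigh(values)
    lam_max = max(eigvals[-1], 0.0)
    floor = -PSD_FLOOR * max(lam_max, 1.0)
    if eigvals[0] >= floor:
        return values
    warnings.warn(
        f"clipping negative kernel eigenvalues (min {eigvals[0]:.3e}) to zero",
        stacklevel=3,
    )
    clipped = np.clip(eigvals, 0.0, None)
    repaired = (eigvecs * clipped) @ eigvecs.T
    return 0.5 * (repaired + repaired.T)


def linear_kernel_from_similarity(
    S: SimilarityMatrix, normalize: bool = True
) -> KernelMatrix:
    """Linear kernel K = S S^T on the rows of a similarity/profile matrix,
    cosine-normalized by default.  PSD by construction; numerically repaired
    by eigenvalue clipping if rounding pushes an eigenvalue below the floor."""
    K = S.values @ S.values.T
    K = 0.5 * (K + K.T)
    if normalize:
        K = cosine_normalize(K)
    K = _psd_repair(K)
    if normalize:
        np.fill_diagonal(K, 1.0)
    return KernelMatrix(list(S.row_ids), K, normalized=normalize)


def gip_kernel(
    profiles: np.ndarray, ids: Sequence[str], sigma: float
) -> KernelMatrix:
    """Gaussian interaction-profile kernel.

    K(i,j) = exp(-||v_i - v_j||^2 / (2 sigma^2)) on fully-observed affinity
    profiles (rows).  The diagonal is exactly 1 and the kernel needs no
    further normalization.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    profiles = np.asarray(profiles, dtype=float)
    if not np.all(np.isfinite(profiles)):
        raise ValueError("profiles must be fully observed (impute first)")
    d2 = cdist(profiles, profiles, metric="sqeuclidean")
    K = np.exp(-d2 / (2.0 * sigma**2))
    K = 0.5 * (K + K.T)
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(list(ids), K, normalized=True)


def sigma_grid_from_distances(
    profiles: np.ndarray, quantiles: Sequence[float] = (0.1, 0.5, 0.9)
) -> np.ndarray:
    """Candidate Gaussian widths: empirical quantiles (linear interpolation)
    of the off-diagonal pairwise Euclidean distances between profiles."""
    profiles = np.asarray(profiles, dtype=float)
    if profiles.shape[0] < 2:
        raise ValueError("need at least two profiles")
    dists = pdist(profiles, metric="euclidean")
    if dists.max() == 0:
        raise ValueError("all profiles identical: candidate sigmas would be zero")
    return np.quantile(dists, quantiles)


def pairwise_distances_full(profiles: np.ndarray) -> np.ndarray:
    """Square Euclidean distance matrix (convenience for diagnostics)."""
    return squareform(pdist(np.asarray(profiles, dtype=float)))
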