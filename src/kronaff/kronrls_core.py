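"""KronRLS: kernel ridge regression with a Kronecker-product pairwise kernel.

The pairwise kernel over compound-protein pairs is K = K_D (x) K_P, and the
dual coefficients solve (K + lambda I) alpha = y.  Materializing K is
quadratic in n_D * n_P, so training instead uses the eigendecompositions
K_D = U_D S_D U_D^T and K_P = U_P S_P U_P^T:

    alpha = vec(U_P C U_D^T),
    vec(C) = (S_D (x) S_P + lambda I)^{-1} vec(U_P^T Y^T U_D),

with vec the column-stacking operator and Y the n_D x n_P label matrix
(drugs in rows).  Predictions for a query pair are
f = k_P (U_P C U_D^T) k_D^T where k_D, k_P are the query's similarity
vectors to the training compounds and proteins.

The eigendecomposition shortcut requires a complete label matrix, so
missing affinities are first filled by :func:`impute_missing` -- a weighted
row (compound) average where each observed protein contributes according to
its similarity (normalized Smith-Waterman score) to the protein whose value
is missing.  Imputed cells are tracked by the caller and excluded from any
performance assessment.

:func:`solve_explicit` materializes the full Kronecker system and exists as
the small-scale reference implementation against which the fast path is
verified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compound_kernels import KernelMatrix
from .io_formats import BioactivityMatrix

__all__ = [
    "KronRLSModel",
    "impute_missing",
    "solve_explicit",
    "fit",
    "fit_from_eigh",
    "eigh_kernel",
    "predict",
    "predict_matrix",
]

EIG_CLIP = 1e-8
EXPLICIT_GUARD = 4096


@dataclass
class KronRLSModel:
    """Fitted KronRLS model.

    ``dual_matrix`` is C (n_P x n_D); the flat dual vector alpha is
    vec(U_P C U_D^T), consistent with y = vec(Y^T) ordering (drug-major).
    """

    lam: float
    drug_eigvecs: np.ndarray
    drug_eigvals: np.ndarray
    protein_eigvecs: np.ndarray
    protein_eigvals: np.ndarray
    dual_matrix: np.ndarray
    drug_ids: list[str]
    protein_ids: list[str]

    @property
    def coefficient_matrix(self) -> np.ndarray:
        """A = U_P C U_D^T (n_P x n_D); predictions are k_P A k_D^T."""
        return self.protein_eigvecs @ self.dual_matrix @ self.drug_eigvecs.T

    @property
    def alpha(self) -> np.ndarray:
        """Flat dual vector in drug-major (vec(Y^T)) ordering."""
        return self.coefficient_matrix.flatten(order="F")


def impute_missing(
    Y: BioactivityMatrix, protein_similarity: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Fill missing affinities by the similarity-weighted row average.

    For a missing cell (i, j) the imputed value is
    sum_k s(j,k) Y(i,k) / sum_k s(j,k) over proteins k observed in row i.
    Fallback chain for degenerate cases: weighted row mean -> unweighted row
    mean -> column mean -> global mean of observed entries.

    Returns ``(values, observed)`` where ``values`` is fully observed and
    ``observed`` is the original mask (imputed cells must be excluded from
    any performance assessment).
    """
    S = np.asarray(protein_similarity, dtype=float)
    n_P = Y.n_proteins
    if S.shape != (n_P, n_P):
        raise ValueError(
            f"protein similarity must be {n_P}x{n_P}, got {S.shape}"
        )
    values = Y.values.copy()
    observed = Y.observed.copy()
    if observed.all():
        return values, observed
    if not observed.any():
        raise ValueError("cannot impute a matrix with no observed entries")
    global_mean = values[observed].mean()
    col_sums = np.where(observed, values, 0.0).sum(axis=0)
    col_counts = observed.sum(axis=0)
    col_means = np.divide(
        col_sums, col_counts, out=np.full(n_P, np.nan), where=col_counts > 0
    )
    for i in range(Y.n_drugs):
        obs = observed[i]
        missing = np.flatnonzero(~obs)
        if missing.size == 0:
            continue
        if not obs.any():
            # whole compound unmeasured: column mean, then global mean
            for j in missing:
                values[i, j] = (
                    col_means[j] if np.isfinite(col_means[j]) else global_mean
                )
            continue
        row_vals = values[i, obs]
        row_mean = row_vals.mean()
        W = S[np.ix_(missing, obs)]
        wsum = W.sum(axis=1)
        weighted = np.divide(
            W @ row_vals, wsum, out=np.full(missing.size, np.nan), where=wsum > 0
        )
        values[i, missing] = np.where(np.isfinite(weighted), weighted, row_mean)
    return values, observed


def _as_values(K) -> np.ndarray:
    return K.values if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)


def solve_explicit(K_D, K_P, Y_complete: np.ndarray, lam: float) -> np.ndarray:
    """Reference dense solve of (K_D (x) K_P + lambda I) alpha = vec(Y^T).

    Materializes the full Kronecker kernel; guarded to small problems and
    used as the correctness oracle for the eigendecomposition path.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    KD = _as_values(K_D)
    KP = _as_values(K_P)
    Y = np.asarray(Y_complete, dtype=float)
    n_D, n_P = KD.shape[0], KP.shape[0]
    if n_D * n_P > EXPLICIT_GUARD:
        raise ValueError(
            f"explicit solver limited to {EXPLICIT_GUARD} pairs, got {n_D * n_P}"
        )
    if Y.shape != (n_D, n_P):
        raise ValueError("Y shape must match the kernels")
    K = np.kron(KD, KP)
    y = Y.flatten()  # vec(Y^T): drug-major ordering
    return np.linalg.solve(K + lam * np.eye(n_D * n_P), y)


def eigh_kernel(K) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric eigendecomposition with small negative eigenvalues clipped
    to zero (numerical PSD floor)."""
    values = _as_values(K)
    eigvals, eigvecs = np.linalg.eigh(values)
    lam_max = max(eigvals[-1], 0.0)
    floor = -EIG_CLIP * max(lam_max, 1.0)
    if eigvals[0] < floor:
        raise ValueError(f"kernel not PSD: min eigenvalue {eigvals[0]:.3e}")
    eigvals = np.clip(eigvals, 0.0, None)
    return eigvals, eigvecs


def fit_from_eigh(
    eig_D: tuple[np.ndarray, np.ndarray],
    eig_P: tuple[np.ndarray, np.ndarray],
    Y_complete: np.ndarray,
    lam: float,
    drug_ids=None,
    protein_ids=None,
) -> KronRLSModel:
    """Fit from precomputed kernel eigendecompositions (grid-search fast path:
    one decomposition serves every lambda)."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    Y = np.asarray(Y_complete, dtype=float)
    if np.isnan(Y).any():
        raise ValueError(
            "label matrix contains missing values; apply impute_missing first"
        )
    sig_D, U_D = eig_D
    sig_P, U_P = eig_P
    M = U_P.T @ Y.T @ U_D  # n_P x n_D in the eigenbases
    C = M / (np.outer(sig_P, sig_D) + lam)
    return KronRLSModel(
        lam=lam,
        drug_eigvecs=U_D,
        drug_eigvals=sig_D,
        protein_eigvecs=U_P,
        protein_eigvals=sig_P,
        dual_matrix=C,
        drug_ids=list(drug_ids) if drug_ids is not None else [],
        protein_ids=list(protein_ids) if protein_ids is not None else [],
    )


def fit(K_D, K_P, Y_complete: np.ndarray, lam: float) -> KronRLSModel:
    """Train KronRLS via the factor-kernel eigendecompositions."""
    drug_ids = K_D.ids if isinstance(K_D, KernelMatrix) else None
    protein_ids = K_P.ids if isinstance(K_P, KernelMatrix) else None
    return fit_from_eigh(
        eigh_kernel(K_D),
        eigh_kernel(K_P),
        Y_complete,
        lam,
        drug_ids=drug_ids,
        protein_ids=protein_ids,
    )


def predict(model: KronRLSModel, k_D_vec: np.ndarray, k_P_vec: np.ndarray) -> float:
    """Predict the affinity of one query pair from its kernel vectors to the
    training compounds and proteins."""
    k_D = np.asarray(k_D_vec, dtype=float)
    k_P = np.asarray(k_P_vec, dtype=float)
    A = model.coefficient_matrix
    if k_D.shape != (A.shape[1],) or k_P.shape != (A.shape[0],):
        raise ValueError("query kernel vector lengths must match training axes")
    return float(k_P @ A @ k_D)


def predict_matrix(
    model: KronRLSModel, K_D_query: np.ndarray, K_P_query: np.ndarray
) -> np.ndarray:
    """Batch predictions: rows of ``K_D_query``/``K_P_query`` are query kernel
    vectors; returns an (n_query_drugs, n_query_proteins) matrix.  With the
    training kernel matrices themselves this returns the fitted values."""
    KDq = np.atleast_2d(np.asarray(K_D_query, dtype=float))
    KPq = np.atleast_2d(np.asarray(K_P_query, dtype=float))
    A = model.coefficient_matrix
    return KDq @ A.T @ KPq.T
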