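"""Protein-side kernels.

Four families are provided:

* **SW**: a square matrix of normalized Smith-Waterman local-alignment
  scores, SW(i,j) / sqrt(SW(i,i) SW(j,j)), turned into a linear kernel
  K_P = S_P S_P^T.
* **SW+** (extended target profile): rows of normalized SW scores against a
  large external reference proteome rather than only the study's proteins;
  the kernel is again the linear kernel on those rectangular profiles.
* **GS** (generic string kernel): compares every pair of substrings up to
  length L, weighting each comparison by a Gaussian in the positional shift
  of the two substrings and a Gaussian in the distance between their
  concatenated per-residue descriptor vectors (BLOSUM50 rows by default).
* **GIP**: Gaussian interaction-profile kernel on a protein's column of
  (imputed) affinities; delegates to :func:`kronaff.compound_kernels.gip_kernel`.

Precomputed external similarity matrices (e.g. 3D-structure alignment
scores) are supported through self-score normalization plus the same linear
kernel, and an exact identity kernel is available as the featureless
fallback for the scenario where only drug-side information exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner
from scipy.spatial.distance import cdist

from .compound_kernels import (
    KernelMatrix,
    SimilarityMatrix,
    cosine_normalize,
    linear_kernel_from_similarity,
    _psd_repair,
)
from .io_formats import (
    STANDARD_AMINO_ACIDS,
    SequenceSet,
    SubstitutionMatrix,
    load_blosum,
)

__all__ = [
    "AlignmentParams",
    "GSKernelParams",
    "AminoAcidDescriptorTable",
    "blosum_descriptor_table",
    "smith_waterman_score",
    "normalized_sw_similarity",
    "sw_similarity_matrix",
    "sw_kernel",
    "sw_plus_profiles",
    "gs_kernel",
    "gs_kernel_matrix",
    "identity_protein_kernel",
    "normalize_by_self_scores",
    "kernel_from_precomputed_similarity",
]


@dataclass
class AlignmentParams:
    """Smith-Waterman scoring scheme.

    Affine gaps: a gap of length k costs ``gap_open + (k - 1) * gap_extend``.
    Defaults are the EMBOSS water defaults for BLOSUM50 (open 10, extend 0.5).
    """

    substitution: SubstitutionMatrix = field(default_factory=load_blosum)
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        self._aligner = PairwiseAligner(
            mode="local",
            open_gap_score=-self.gap_open,
            extend_gap_score=-self.gap_extend,
        )
        from Bio.Align import substitution_matrices

        arr = substitution_matrices.Array(
            alphabet=self.substitution.alphabet,
            dims=2,
            data=np.asarray(self.substitution.scores, dtype=float),
        )
        self._aligner.substitution_matrix = arr


@dataclass
class GSKernelParams:
    """Generic string kernel parameters: max substring length L, positional
    width sigma_p, and content (descriptor) width sigma_c."""

    L: int = 2
    sigma_p: float = 1.0
    sigma_c: float = 1.0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.sigma_p <= 0 or self.sigma_c <= 0:
            raise ValueError("sigma_p and sigma_c must be positive")


@dataclass
class AminoAcidDescriptorTable:
    """Per-residue descriptor vectors psi(a) of a fixed dimension d.

    The default maps each residue to its BLOSUM50 row restricted to the 20
    standard residues (d = 20).  Residues outside the table (the 'X'
    wildcard when the table lacks it) get the zero vector.
    """

    alphabet: str
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape[0] != len(self.alphabet):
            raise ValueError("one descriptor vector required per residue")
        self._index = {a: i for i, a in enumerate(self.alphabet)}

    @property
    def d(self) -> int:
        return self.vectors.shape[1]

    def encode(self, sequence: str) -> np.ndarray:
        """Stack psi(residue) for each position -> (len(sequence), d)."""
        out = np.zeros((len(sequence), self.d))
        for i, a in enumerate(sequence):
            j = self._index.get(a)
            if j is not None:
                out[i] = self.vectors[j]
        return out


def blosum_descriptor_table(
    substitution: SubstitutionMatrix | None = None,
) -> AminoAcidDescriptorTable:
    """Descriptor table whose vectors are substitution-matrix rows over the
    20 standard residues."""
    sub = substitution if substitution is not None else load_blosum()
    cols = [sub.alphabet.index(a) for a in STANDARD_AMINO_ACIDS]
    rows = [a for a in sub.alphabet if a in set(STANDARD_AMINO_ACIDS + "X")]
    vectors = np.array([[sub.scores[sub.alphabet.index(r), c] for c in cols] for r in rows])
    return AminoAcidDescriptorTable("".join(rows), vectors)


def smith_waterman_score(s1: str, s2: str, params: AlignmentParams | None = None) -> float:
    """Optimal local-alignment score under affine gaps (dynamic programming)."""
    if not s1 or not s2:
        raise ValueError("sequences must be non-empty")
    params = params or AlignmentParams()
    return float(params._aligner.score(s1, s2))


def normalized_sw_similarity(
    s_i: str, s_j: str, params: AlignmentParams | None = None
) -> float:
    """SW(i,j) / sqrt(SW(i,i) SW(j,j)); exactly 1 for identical sequences."""
    params = params or AlignmentParams()
    sii = smith_waterman_score(s_i, s_i, params)
    sjj = smith_waterman_score(s_j, s_j, params)
    if sii <= 0 or sjj <= 0:
        raise ValueError("self-alignment score must be positive")
    if s_i == s_j:
        return 1.0
    return smith_waterman_score(s_i, s_j, params) / np.sqrt(sii * sjj)


def sw_similarity_matrix(
    seqs: SequenceSet, params: AlignmentParams | None = None
) -> SimilarityMatrix:
    """Square normalized-SW similarity matrix S_P-SW over a sequence set."""
    params = params or AlignmentParams()
    n = len(seqs)
    self_scores = np.array(
        [smith_waterman_score(s, s, params) for s in seqs.sequences]
    )
    if np.any(self_scores <= 0):
        raise ValueError("self-alignment score must be positive")
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            raw = smith_waterman_score(seqs.sequences[i], seqs.sequences[j], params)
            values[i, j] = values[j, i] = raw / np.sqrt(
                self_scores[i] * self_scores[j]
            )
    return SimilarityMatrix(list(seqs.protein_ids), list(seqs.protein_ids), values)


def sw_kernel(
    seqs: SequenceSet, params: AlignmentParams | None = None
) -> KernelMatrix:
    """KP-SW: linear kernel on the rows of the normalized SW matrix."""
    return linear_kernel_from_similarity(sw_similarity_matrix(seqs, params))


def sw_plus_profiles(
    targets: SequenceSet,
    reference: SequenceSet,
    params: AlignmentParams | None = None,
) -> SimilarityMatrix:
    """Extended target profiles: normalized SW scores of each target against
    every protein of a larger reference proteome (n_targets x n_reference).
    The KP-SW+ kernel is the linear kernel on these rows."""
    params = params or AlignmentParams()
    if len(targets) == 0 or len(reference) == 0:
        raise ValueError("target and reference sets must be non-empty")
    t_self = np.array([smith_waterman_score(s, s, params) for s in targets.sequences])
    r_self = np.array([smith_waterman_score(s, s, params) for s in reference.sequences])
    values = np.empty((len(targets), len(reference)))
    for i, ts in enumerate(targets.sequences):
        for l, rs in enumerate(reference.sequences):
            if ts == rs:
                values[i, l] = 1.0
            else:
                values[i, l] = smith_waterman_score(ts, rs, params) / np.sqrt(
                    t_self[i] * r_self[l]
                )
    return SimilarityMatrix(
        list(targets.protein_ids), list(reference.protein_ids), values
    )


def gs_kernel(
    s: str,
    s_prime: str,
    params: GSKernelParams,
    table: AminoAcidDescriptorTable | None = None,
) -> float:
    """Generic string kernel between two sequences.

    Sums, over substring lengths l = 1..L and all 0-based start offsets
    (i, j), the product of a positional-shift Gaussian
    exp(-(i-j)^2 / (2 sigma_p^2)) and a content Gaussian on the squared
    distance between the concatenated descriptor encodings of the two
    substrings.  Lengths exceeding either sequence contribute nothing, so
    any L >= 1 is valid.
    """
    table = table if table is not None else blosum_descriptor_table()
    A = table.encode(s)
    B = table.encode(s_prime)
    ns, nt = len(s), len(s_prime)
    # Base position-position squared descriptor distances.
    D = cdist(A, B, metric="sqeuclidean")
    offsets = np.subtract.outer(np.arange(ns), np.arange(nt))
    P = np.exp(-(offsets.astype(float) ** 2) / (2.0 * params.sigma_p**2))
    total = 0.0
    Dl = None
    for l in range(1, params.L + 1):
        if l > ns or l > nt:
            break
        # Dl[i, j] = sum_t D[i+t, j+t] for t in 0..l-1 (substring distance).
        Dl = D if l == 1 else Dl[:-1, :-1] + D[l - 1 :, l - 1 :]
        total += float(
            np.sum(P[: ns - l + 1, : nt - l + 1] * np.exp(-Dl / (2.0 * params.sigma_c**2)))
        )
    return total


def gs_kernel_matrix(
    seqs: SequenceSet,
    params: GSKernelParams,
    table: AminoAcidDescriptorTable | None = None,
) -> KernelMatrix:
    """Pairwise GS kernel over a sequence set, cosine-normalized."""
    table = table if table is not None else blosum_descriptor_table()
    n = len(seqs)
    values = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            values[i, j] = values[j, i] = gs_kernel(
                seqs.sequences[i], seqs.sequences[j], params, table
            )
    values = cosine_normalize(values)
    values = _psd_repair(values)
    np.fill_diagonal(values, 1.0)
    return KernelMatrix(list(seqs.protein_ids), values, normalized=True)


def identity_protein_kernel(protein_ids) -> KernelMatrix:
    """Exact identity kernel: the featureless fallback when no protein
    descriptors are available (each protein similar only to itself)."""
    ids = list(protein_ids)
    return KernelMatrix(ids, np.eye(len(ids)), normalized=True)


def normalize_by_self_scores(S: SimilarityMatrix) -> SimilarityMatrix:
    """s(i,j) / sqrt(s(i,i) s(j,j)) for a square raw-score matrix (used for
    imported 3D-structure similarity scores)."""
    if not S.is_square:
        raise ValueError("self-score normalization requires a square matrix")
    diag = np.diag(S.values)
    if np.any(diag <= 0):
        raise ValueError("self-scores must be positive")
    values = S.values / np.sqrt(np.outer(diag, diag))
    return SimilarityMatrix(list(S.row_ids), list(S.col_ids), values)


def kernel_from_precomputed_similarity(
    S: SimilarityMatrix, self_normalize: bool = True
) -> KernelMatrix:
    """Linear kernel from an externally computed similarity matrix (e.g.
    3D structural alignment scores), optionally self-score normalized."""
    if self_normalize and S.is_square:
        S = normalize_by_self_scores(S)
    return linear_kernel_from_similarity(S)
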