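"""Readers and writers for the external artifacts of the pipeline.

All tabular artifacts are labeled TSV by default (comma dialect available via
``sep=","``): bioactivity matrices with drug rows and protein columns,
binary fingerprint tables, square or rectangular similarity matrices, and
kernel matrices.  Protein sequences are plain FASTA; substitution matrices
use the NCBI flat-file layout.

Bioactivity values are pK_i, i.e. -log10 of the inhibition constant in molar
units; no unit conversion is performed on read or write.  Missing cells are
an empty string or ``NA`` on read and are written back as ``NA``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "BioactivityMatrix",
    "FingerprintSet",
    "SequenceSet",
    "SubstitutionMatrix",
    "STANDARD_AMINO_ACIDS",
    "read_bioactivity_matrix",
    "write_bioactivity_matrix",
    "read_fingerprints",
    "read_fasta",
    "write_fasta",
    "read_similarity_matrix",
    "write_kernel",
    "write_predictions",
    "read_substitution_matrix",
    "load_blosum",
]

STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
MISSING_TOKENS = ("", "NA")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class BioactivityMatrix:
    """Sparse drug x protein binding-affinity matrix on the pK_i scale.

    ``values`` is dense with NaN in unobserved cells; ``observed`` is the
    boolean mask of measured entries.  Rows are drugs, columns proteins.
    """

    drug_ids: list[str]
    protein_ids: list[str]
    values: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        _check_unique(self.drug_ids, "drug")
        _check_unique(self.protein_ids, "protein")
        shape = (len(self.drug_ids), len(self.protein_ids))
        if self.values.shape != shape or self.observed.shape != shape:
            raise ValueError(
                f"shape mismatch: ids imply {shape}, got values "
                f"{self.values.shape} and mask {self.observed.shape}"
            )
        if not np.all(np.isfinite(self.values[self.observed])):
            raise ValueError("observed cells must hold finite values")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())

    def copy(self) -> "BioactivityMatrix":
        return BioactivityMatrix(
            list(self.drug_ids),
            list(self.protein_ids),
            self.values.copy(),
            self.observed.copy(),
        )

    def mask_entries(self, entries: Iterable[tuple[int, int]]) -> "BioactivityMatrix":
        """Return a copy with the given (drug, protein) cells marked missing."""
        out = self.copy()
        for d, p in entries:
            out.observed[d, p] = False
            out.values[d, p] = np.nan
        return out

    def mask_drugs(self, drug_indices: Iterable[int]) -> "BioactivityMatrix":
        """Return a copy with entire drug rows marked missing."""
        out = self.copy()
        idx = list(drug_indices)
        out.observed[idx, :] = False
        out.values[idx, :] = np.nan
        return out


@dataclass
class FingerprintSet:
    """Binary structural fingerprints, one row per compound."""

    drug_ids: list[str]
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits)
        _check_unique(self.drug_ids, "drug")
        if self.bits.ndim != 2 or self.bits.shape[0] != len(self.drug_ids):
            raise ValueError("bits must be a (n_drugs, B) matrix")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("fingerprint bits must be 0 or 1")
        self.bits = self.bits.astype(np.uint8)

    @property
    def n_bits(self) -> int:
        return self.bits.shape[1]


@dataclass
class SequenceSet:
    """Protein amino-acid sequences in a fixed order."""

    protein_ids: list[str]
    sequences: list[str]
    allow_x: bool = True

    def __post_init__(self) -> None:
        _check_unique(self.protein_ids, "protein")
        if len(self.sequences) != len(self.protein_ids):
            raise ValueError("one sequence required per protein id")
        alphabet = set(STANDARD_AMINO_ACIDS + ("X" if self.allow_x else ""))
        for pid, seq in zip(self.protein_ids, self.sequences):
            if not seq:
                raise ValueError(f"empty sequence for {pid!r}")
            bad = sorted(set(seq) - alphabet)
            if bad:
                raise ValueError(
                    f"sequence {pid!r} contains unsupported residues: {bad}"
                )

    def __len__(self) -> int:
        return len(self.protein_ids)


@dataclass
class SubstitutionMatrix:
    """Symmetric residue substitution scores (e.g. BLOSUM50)."""

    alphabet: str
    scores: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        n = len(self.alphabet)
        if self.scores.shape != (n, n):
            raise ValueError("scores must be square over the alphabet")
        if not np.allclose(self.scores, self.scores.T):
            raise ValueError("substitution matrix must be symmetric")
        diag = np.diag(self.scores)
        std = [i for i, a in enumerate(self.alphabet) if a in STANDARD_AMINO_ACIDS]
        if np.any(diag[std] <= 0):
            raise ValueError("diagonal must be positive for standard residues")
        self._index = {a: i for i, a in enumerate(self.alphabet)}

    def score(self, a: str, b: str) -> float:
        """Pair score; residues absent from the alphabet score 0 (mismatch)."""
        try:
            return float(self.scores[self._index[a], self._index[b]])
        except KeyError:
            return 0.0

    def __contains__(self, residue: str) -> bool:
        return residue in self._index


def _read_rows(path, sep: str) -> list[list[str]]:
    with open(path, newline="") as fh:
        return [row for row in csv.reader(fh, delimiter=sep)]


def read_bioactivity_matrix(
    path,
    missing_tokens: Sequence[str] = MISSING_TOKENS,
    sep: str = "\t",
) -> BioactivityMatrix:
    """Parse a labeled affinity table: header row of protein ids, first
    column of drug ids, cells either decimal pK_i or a missing token."""
    rows = _read_rows(path, sep)
    if not rows:
        raise ValueError(f"{path}: empty file")
    protein_ids = [c.strip() for c in rows[0][1:]]
    width = len(rows[0])
    drug_ids: list[str] = []
    values = np.full((len(rows) - 1, len(protein_ids)), np.nan)
    observed = np.zeros_like(values, dtype=bool)
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ValueError(f"{path}: row {r} has {len(row)} fields, expected {width}")
        drug_ids.append(row[0].strip())
        for c, cell in enumerate(row[1:]):
            tok = cell.strip()
            if tok in missing_tokens:
                continue
            values[r - 2, c] = float(tok)
            observed[r - 2, c] = True
    return BioactivityMatrix(drug_ids, protein_ids, values, observed)


def write_bioactivity_matrix(path, matrix: BioactivityMatrix, sep: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep)
        w.writerow([""] + matrix.protein_ids)
        for i, did in enumerate(matrix.drug_ids):
            row = [
                repr(float(v)) if obs else "NA"
                for v, obs in zip(matrix.values[i], matrix.observed[i])
            ]
            w.writerow([did] + row)


def read_fingerprints(path, sep: str = "\t") -> FingerprintSet:
    """Parse a fingerprint table: one row per compound, id then 0/1 cells."""
    rows = _read_rows(path, sep)
    drug_ids, bits = [], []
    for r, row in enumerate(rows, start=1):
        if not row:
            continue
        drug_ids.append(row[0].strip())
        vec = []
        for c, cell in enumerate(row[1:], start=2):
            tok = cell.strip()
            if tok not in ("0", "1"):
                raise ValueError(
                    f"{path}: non-binary cell {tok!r} at row {r}, column {c}"
                )
            vec.append(int(tok))
        bits.append(vec)
    lengths = {len(v) for v in bits}
    if len(lengths) > 1:
        raise ValueError(f"{path}: inconsistent fingerprint lengths {sorted(lengths)}")
    return FingerprintSet(drug_ids, np.array(bits, dtype=np.uint8))


def write_fingerprints(path, fps: FingerprintSet, sep: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep)
        for did, row in zip(fps.drug_ids, fps.bits):
            w.writerow([did] + [int(b) for b in row])


def read_fasta(path, allow_x: bool = True) -> SequenceSet:
    """Read FASTA records; the id is the first whitespace token of the header."""
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    return SequenceSet(ids, seqs, allow_x=allow_x)


def write_fasta(path, seqs: SequenceSet, width: int = 70) -> None:
    with open(path, "w") as fh:
        for pid, seq in zip(seqs.protein_ids, seqs.sequences):
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_similarity_matrix(path, sep: str = "\t"):
    """Read a labeled similarity matrix (square or rectangular).

    Returns a :class:`kronaff.compound_kernels.SimilarityMatrix`.
    """
    from .compound_kernels import SimilarityMatrix

    rows = _read_rows(path, sep)
    if not rows:
        raise ValueError(f"{path}: empty file")
    col_ids = [c.strip() for c in rows[0][1:]]
    row_ids = [row[0].strip() for row in rows[1:]]
    values = np.array([[float(c) for c in row[1:]] for row in rows[1:]])
    return SimilarityMatrix(row_ids, col_ids, values)


def write_kernel(path, kernel, sep: str = "\t") -> None:
    """Write a labeled square kernel matrix at full float precision."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep)
        w.writerow([""] + list(kernel.ids))
        for i, rid in enumerate(kernel.ids):
            w.writerow([rid] + [repr(float(v)) for v in kernel.values[i]])


def write_predictions(path, triplets, sep: str = "\t") -> None:
    """Write (drug_id, protein_id, predicted_pKi) rows with a header."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep)
        w.writerow(["drug_id", "protein_id", "predicted_pKi"])
        for did, pid, val in triplets:
            w.writerow([did, pid, repr(float(val))])


def read_predictions(path, sep: str = "\t") -> list[tuple[str, str, float]]:
    rows = _read_rows(path, sep)
    return [(r[0], r[1], float(r[2])) for r in rows[1:] if r]


def read_substitution_matrix(path) -> SubstitutionMatrix:
    """Read an NCBI-style flat substitution matrix file."""
    with open(path) as fh:
        arr = substitution_matrices.read(fh)
    return _from_biopython(arr)


def load_blosum(name: str = "BLOSUM50") -> SubstitutionMatrix:
    """Load a named substitution matrix from Biopython's bundled set."""
    return _from_biopython(substitution_matrices.load(name))


def _from_biopython(arr) -> SubstitutionMatrix:
    alphabet = "".join(arr.alphabet)
    return SubstitutionMatrix(alphabet, np.asarray(arr))
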