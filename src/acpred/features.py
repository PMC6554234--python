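"""Sequence feature encodings: binary profile, reduced-alphabet k-mer/SVD.

Two complementary representations turn a variable-length peptide into a
fixed-length vector:

* **Binary profile feature (BPF)** — position-wise one-hot encoding of the
  first ``k`` N-terminal residues over the 20-letter alphabet (20·k dims,
  140 at the default k=7).  Captures the terminal residues, which matter
  for peptide bioactivity.
* **k-mer sparse matrix + SVD** — the 20 residues are first collapsed into
  7 physicochemical groups (by dipole moment and side-chain volume), the
  reduced sequence is scanned into a binary matrix with one row per
  possible reduced k-mer (7^k) and one column per window (L−k+1), and the
  matrix is compressed to a single 7^k vector (343 at k=3) via its leading
  singular pair.  Retains composition together with coarse order/position
  information.

Concatenating the two gives the 483-dimensional conjoined vector the
classifiers consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .peptides import AMINO_ACIDS, LabeledDataset, Peptide

logger = logging.getLogger(__name__)

#: Reduced 7-group alphabet over dipole moment / side-chain volume:
#: 1:{A,G,V} 2:{I,L,F,P} 3:{Y,M,T,S} 4:{H,N,Q,W} 5:{R,K} 6:{D,E} 7:{C}
REDUCTION_GROUPS: dict[str, int] = {}
for _group, _members in enumerate(("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C"), 1):
    for _aa in _members:
        REDUCTION_GROUPS[_aa] = _group
assert len(REDUCTION_GROUPS) == 20

N_GROUPS = 7
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

VALID_ENCODINGS = ("bpf", "kmer_svd", "conjoined")


@dataclass(frozen=True)
class ReducedSequence:
    """A peptide re-expressed over the 7-group reduced alphabet."""

    symbols: str  # characters '1'..'7', same length as the source peptide
    source_id: str

    def __post_init__(self):
        if not self.symbols or any(c not in "1234567" for c in self.symbols):
            raise ValueError("reduced symbols must be a non-empty string over 1..7")

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class KmerMatrix:
    """Binary k-mer occurrence matrix for one reduced sequence.

    ``entries`` has shape (7^k, L−k+1); column j holds a single 1 in the
    row indexing the k-mer that starts at position j+1 of the sequence.
    """

    entries: np.ndarray
    k: int
    source_id: str

    def __post_init__(self):
        if self.entries.shape[0] != N_GROUPS**self.k:
            raise ValueError("row count must be 7^k")

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape


@dataclass(frozen=True)
class FeatureVector:
    """A fixed-length feature vector tagged with its encoding provenance."""

    values: np.ndarray
    encoding: str  # bpf | kmer_svd | conjoined
    source_id: str
    label: int | None = None

    def __post_init__(self):
        if self.encoding not in VALID_ENCODINGS:
            raise ValueError(f"unknown encoding {self.encoding!r}")
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float)
        )

    def __len__(self) -> int:
        return len(self.values)


def reduce_alphabet(peptide: Peptide) -> ReducedSequence:
    """Map a peptide onto the 7-group reduced alphabet, position by position.

    The mapping is total over the 20 standard residues and preserves length.
    """
    symbols = "".join(str(REDUCTION_GROUPS[aa]) for aa in peptide.residues)
    return ReducedSequence(symbols=symbols, source_id=peptide.id)


def encode_bpf(peptide: Peptide, k: int = 7) -> FeatureVector:
    """Binary profile feature: one-hot of the first k N-terminal residues.

    Output is the position-major concatenation of k one-hot blocks of
    length 20 (alphabetical residue order), so 20·k components in total.
    Peptides shorter than k contribute all-zero blocks for the missing
    positions, keeping the fixed-length contract.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    values = np.zeros(20 * k, dtype=float)
    for pos, aa in enumerate(peptide.residues[:k]):
        values[20 * pos + _AA_INDEX[aa]] = 1.0
    return FeatureVector(values, "bpf", peptide.id, peptide.label)


def kmer_row_index(kmer: str) -> int:
    """Row index of a reduced k-mer: base-7 positional code, 0-based.

    The k-mer (g1, …, gk) over groups 1–7 maps to Σ (g_j − 1)·7^(k−j),
    most-significant digit first.
    """
    index = 0
    for ch in kmer:
        index = index * N_GROUPS + (int(ch) - 1)
    return index


def build_kmer_matrix(reduced: ReducedSequence, k: int = 3) -> KmerMatrix:
    """Scan the reduced sequence into its binary 7^k × (L−k+1) k-mer matrix.

    Column j (0-based) marks which of the 7^k possible k-mers occupies the
    window starting at position j+1; every column therefore holds exactly
    one 1 and the matrix holds L−k+1 ones in total.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    L = len(reduced)
    if L < k:
        raise ValueError(
            f"sequence {reduced.source_id!r} too short for k-mer matrix "
            f"(length {L} < k={k})"
        )
    n_windows = L - k + 1
    entries = np.zeros((N_GROUPS**k, n_windows), dtype=float)
    for j in range(n_windows):
        entries[kmer_row_index(reduced.symbols[j : j + k]), j] = 1.0
    return KmerMatrix(entries=entries, k=k, source_id=reduced.source_id)


def svd_reduce(matrix: KmerMatrix, strategy: str = "leading") -> FeatureVector:
    """Compress a k-mer matrix into a single 7^k-dimensional vector via SVD.

    With M = U·Σ·Vᵀ, strategy ``"leading"`` returns u₁·σ₁ — the best
    rank-1 summary of M living in k-mer space; ``"sum"`` returns Σᵢ uᵢ·σᵢ.
    Sign convention: the component of largest absolute value is made
    non-negative (ties broken by lowest index), so the output is
    deterministic.  An all-zero matrix yields an all-zero vector with a
    logged warning.
    """
    M = matrix.entries
    if not M.any():
        logger.warning(
            "all-zero k-mer matrix for %s: returning zero vector", matrix.source_id
        )
        return FeatureVector(np.zeros(M.shape[0]), "kmer_svd", matrix.source_id)
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    if strategy == "leading":
        vec = U[:, 0] * s[0]
    elif strategy == "sum":
        vec = U @ s
    else:
        raise ValueError(f"unknown SVD strategy {strategy!r}")
    vec = _fix_sign(vec)
    return FeatureVector(vec, "kmer_svd", matrix.source_id)


def _fix_sign(vec: np.ndarray) -> np.ndarray:
    # make the largest-magnitude component non-negative; ties -> lowest index
    pivot = int(np.argmax(np.abs(vec)))
    if vec[pivot] < 0:
        vec = -vec
    return vec


def conjoin_features(bpf: FeatureVector, kmer: FeatureVector) -> FeatureVector:
    """Concatenate [BPF ‖ k-mer/SVD] into one conjoined vector (483 dims
    at the defaults), BPF block first; the label is propagated."""
    if bpf.encoding != "bpf":
        raise ValueError(f"first argument must be a bpf vector, got {bpf.encoding!r}")
    if kmer.encoding != "kmer_svd":
        raise ValueError(
            f"second argument must be a kmer_svd vector, got {kmer.encoding!r}"
        )
    if bpf.source_id != kmer.source_id:
        raise ValueError(
            f"source mismatch: {bpf.source_id!r} vs {kmer.source_id!r}"
        )
    values = np.concatenate([bpf.values, kmer.values])
    return FeatureVector(values, "conjoined", bpf.source_id, bpf.label)


def encode_peptide(
    peptide: Peptide,
    bpf_k: int = 7,
    kmer_k: int = 3,
    svd_strategy: str = "leading",
) -> FeatureVector:
    """Full encoding of one peptide: BPF ‖ SVD-compressed k-mer matrix."""
    bpf = encode_bpf(peptide, k=bpf_k)
    reduced = reduce_alphabet(peptide)
    kmer = svd_reduce(build_kmer_matrix(reduced, k=kmer_k), strategy=svd_strategy)
    return conjoin_features(bpf, kmer)


def encode_dataset(
    dataset: LabeledDataset,
    bpf_k: int = 7,
    kmer_k: int = 3,
    svd_strategy: str = "leading",
) -> list[FeatureVector]:
    """Encode every peptide of a dataset, in order.

    The encoders fit nothing — encoding is deterministic, label-free and
    per-peptide — so the result can be computed once and reused across
    cross-validation folds without leakage.  Peptides shorter than
    ``kmer_k`` are a hard error; filter them out first if needed.
    """
    too_short = [p.id for p in dataset if len(p) < kmer_k]
    if too_short:
        raise ValueError(
            f"peptides shorter than k={kmer_k} cannot be k-mer encoded: "
            + ", ".join(too_short)
        )
    return [
        encode_peptide(p, bpf_k=bpf_k, kmer_k=kmer_k, svd_strategy=svd_strategy)
        for p in dataset
    ]


def feature_matrix(features: list[FeatureVector]) -> tuple[np.ndarray, np.ndarray]:
    """Stack feature vectors into (X, y); unlabeled entries get label −1."""
    X = np.vstack([f.values for f in features])
    y = np.array([-1 if f.label is None else f.label for f in features], dtype=int)
    return X, y
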