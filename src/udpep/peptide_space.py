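"""The discrete peptide sequence space.

A k-peptide over the 20 canonical amino acids is one point in a space of
20**k level-combinations.  This module fixes the residue alphabet (and
therefore every encoding downstream), enumerates the space, converts
sequences to and from one-hot vectors, and quantifies how far a training
sample sits from a test sample in Hamming distance.

The alphabet is ordered alphabetically by one-letter code.  All indices are
0-based internally; user-facing output always uses residue letters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError, SequenceError

#: Canonical residues, alphabetical by one-letter code.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Number of levels per position (alphabet size).
Q: int = len(AMINO_ACIDS)

#: Residue letter -> 0-based alphabet index.
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

_MAX_ENUM_K = 6  # 20**6 = 6.4e7 sequences; beyond this enumeration is refused


def validate_sequence(seq: str, k: int | None = None) -> str:
    """Validate a peptide sequence, returning it unchanged.

    Raises :class:`SequenceError` naming the offending character and its
    1-based position, or complaining about a length mismatch when ``k`` is
    given.
    """
    if not isinstance(seq, str) or len(seq) == 0:
        raise SequenceError(f"expected a non-empty peptide string, got {seq!r}")
    for pos, ch in enumerate(seq, start=1):
        if ch not in AA_INDEX:
            raise SequenceError(
                f"invalid residue {ch!r} at position {pos} in sequence {seq!r}"
            )
    if k is not None and len(seq) != k:
        raise SequenceError(f"sequence {seq!r} has length {len(seq)}, expected {k}")
    return seq


@dataclass(frozen=True)
class SpaceSpec:
    """The full k-peptide space: 20**k sequences."""

    k: int
    n_total: int = field(init=False)

    def __post_init__(self) -> None:
        if not 1 <= self.k <= _MAX_ENUM_K:
            raise DomainError(f"k must be in [1, {_MAX_ENUM_K}], got {self.k}")
        object.__setattr__(self, "n_total", Q**self.k)


def enumerate_space(k: int) -> Iterator[str]:
    """Yield all 20**k sequences in lexicographic order over the alphabet."""
    spec = SpaceSpec(k)  # bounds check
    for combo in itertools.product(AMINO_ACIDS, repeat=spec.k):
        yield "".join(combo)


def peptide_to_index(seq: str) -> int:
    """Lexicographic rank of ``seq`` within its length's space (base-20)."""
    validate_sequence(seq)
    rank = 0
    for ch in seq:
        rank = rank * Q + AA_INDEX[ch]
    return rank


def index_to_peptide(index: int, k: int) -> str:
    """Inverse of :func:`peptide_to_index` for length ``k``."""
    if not 0 <= index < Q**k:
        raise DomainError(f"index {index} out of range for k={k}")
    out = []
    for _ in range(k):
        index, r = divmod(index, Q)
        out.append(AMINO_ACIDS[r])
    return "".join(reversed(out))


def one_hot_encode(seq: str) -> np.ndarray:
    """Encode a peptide as a length k*20 one-hot vector.

    Block ``i`` (20 entries) encodes residue ``i`` by alphabet index, so a
    tetrapeptide becomes the 80-dimensional vector used by the sequence
    regression models.
    """
    validate_sequence(seq)
    v = np.zeros(len(seq) * Q)
    for i, ch in enumerate(seq):
        v[i * Q + AA_INDEX[ch]] = 1.0
    return v


def one_hot_decode(vector: Sequence[float]) -> str:
    """Recover the unique peptide whose one-hot encoding is ``vector``."""
    v = np.asarray(vector, dtype=float)
    if v.ndim != 1 or v.size == 0 or v.size % Q:
        raise SequenceError(f"vector length {v.size} is not a positive multiple of {Q}")
    out = []
    for i in range(v.size // Q):
        block = v[i * Q : (i + 1) * Q]
        hot = np.flatnonzero(block == 1.0)
        if hot.size != 1 or block.sum() != 1.0:
            raise SequenceError(f"block {i} is not one-hot: {block.tolist()}")
        out.append(AMINO_ACIDS[int(hot[0])])
    return "".join(out)


def encode_matrix(sequences: Iterable[str]) -> np.ndarray:
    """Stack one-hot encodings of equal-length sequences into an (n, k*20) array."""
    seqs = list(sequences)
    if not seqs:
        return np.zeros((0, 0))
    k = len(seqs[0])
    X = np.zeros((len(seqs), k * Q))
    for r, s in enumerate(seqs):
        validate_sequence(s, k)
        for i, ch in enumerate(s):
            X[r, i * Q + AA_INDEX[ch]] = 1.0
    return X


class OneHotPeptideEncoder:
    """Scikit-learn style transformer mapping sequences to one-hot matrices.

    Stateless apart from the sequence length learned in :meth:`fit`, which is
    used only for validation.  Composes with sklearn pipelines.
    """

    def __init__(self) -> None:
        pass

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "OneHotPeptideEncoder":
        if params:
            raise ValueError(f"unknown parameters: {sorted(params)}")
        return self

    def fit(self, X: Iterable[str], y=None) -> "OneHotPeptideEncoder":
        seqs = list(X)
        if not seqs:
            raise SequenceError("cannot fit on an empty sequence collection")
        self.k_ = len(seqs[0])
        for s in seqs:
            validate_sequence(s, self.k_)
        self.n_features_out_ = self.k_ * Q
        return self

    def transform(self, X: Iterable[str]) -> np.ndarray:
        if not hasattr(self, "k_"):
            raise RuntimeError("encoder is not fitted")
        M = encode_matrix(X)
        if M.size and M.shape[1] != self.n_features_out_:
            raise SequenceError(
                f"sequences of length {M.shape[1] // Q} passed to an encoder fitted with k={self.k_}"
            )
        return M

    def fit_transform(self, X: Iterable[str], y=None) -> np.ndarray:
        return self.fit(X).transform(X)

    def inverse_transform(self, M: np.ndarray) -> list[str]:
        return [one_hot_decode(row) for row in np.asarray(M)]


@dataclass(frozen=True)
class HammingSummary:
    """Pairwise Hamming statistics between a train and a test sequence set."""

    mean: float
    min: int
    histogram: dict[int, int]  # distance -> pair count
    n_pairs: int


def hamming_separation(train: Sequence[str], test: Sequence[str]) -> HammingSummary:
    """Summarise Hamming distances over all train x test sequence pairs.

    Distances are computed through the one-hot inner product (matches =
    A_train @ A_test.T), which keeps the full |train| x |test| pair matrix
    tractable for design-scale inputs.
    """
    train = list(train)
    test = list(test)
    if not train or not test:
        raise DomainError("train and test sets must be non-empty")
    k = len(train[0])
    for s in itertools.chain(train, test):
        if len(s) != k:
            raise SequenceError(
                f"sequence {s!r} has length {len(s)}; all sequences must have length {k}"
            )
    A = encode_matrix(train).astype(np.float32)
    B = encode_matrix(test).astype(np.float32)
    matches = A @ B.T  # (n_train, n_test) count of agreeing positions
    dist = (k - matches).astype(np.int64)
    counts = np.bincount(dist.ravel(), minlength=k + 1)
    n_pairs = dist.size
    return HammingSummary(
        mean=float(dist.mean()),
        min=int(dist.min()),
        histogram={d: int(c) for d, c in enumerate(counts)},
        n_pairs=int(n_pairs),
    )


# ---------------------------------------------------------------------------
# File interfaces


def read_sequences(path: str | Path) -> list[str]:
    """Read peptide sequences from FASTA or a one-column CSV (header 'sequence')."""
    path = Path(path)
    if path.suffix.lower() in {".fa", ".fasta", ".faa"}:
        from Bio import SeqIO

        return [validate_sequence(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    df = pd.read_csv(path)
    if "sequence" not in df.columns:
        raise FormatError(f"{path} has no 'sequence' column (found {list(df.columns)})")
    return [validate_sequence(str(s)) for s in df["sequence"]]


def write_sequences(path: str | Path, sequences: Sequence[str], ids: Sequence[str] | None = None) -> None:
    """Write sequences as FASTA (generated IDs ``pep{i:06d}`` when absent) or CSV."""
    path = Path(path)
    if path.suffix.lower() in {".fa", ".fasta", ".faa"}:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        recs = [
            SeqRecord(Seq(s), id=(ids[i] if ids is not None else f"pep{i:06d}"), description="")
            for i, s in enumerate(sequences)
        ]
        seqio_write(recs, str(path), "fasta")
    else:
        pd.DataFrame({"sequence": list(sequences)}).to_csv(path, index=False)
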