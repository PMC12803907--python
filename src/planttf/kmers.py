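"""k-mer relative-frequency encoding of protein sequences.

Each sequence is slid over with a length-k window (step 1). A window is valid
iff all its residues are standard amino acids; the feature value for a k-mer is
its count among valid windows divided by the number of valid windows, so every
row over the full vocabulary sums to 1 (length-invariant embedding). The
vocabulary is the complete lexicographic enumeration of the 20^k k-mers over
``ACDEFGHIKLMNPQRSTVWY``; that ordering is part of persisted model metadata so
feature masks and weights stay aligned across runs.

Matrices for k<=3 are dense; k=4 (160 000 columns) and k=5 (3 200 000 columns)
are assembled as CSR sparse and only the masked sub-matrix is densified.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from functools import cached_property
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .seqio import STANDARD_ALPHABET, LabeledCorpus, ProteinRecord

logger = logging.getLogger(__name__)

MIN_K = 1
MAX_K = 5
#: k sizes above this are encoded sparsely (20^k columns).
_DENSE_K_MAX = 3

_CODE = np.full(128, -1, dtype=np.int64)
for _i, _aa in enumerate(STANDARD_ALPHABET):
    _CODE[ord(_aa)] = _i


@dataclass(frozen=True)
class KmerVocabulary:
    """Ordered enumeration of all k-mers of length ``k`` over the 20-letter alphabet.

    ``kmers`` is materialized lazily (for k=5 there are 3.2 million strings);
    index lookup is arithmetic base-20 positional encoding, identical to the
    position in the lexicographic enumeration.
    """

    k: int

    def __post_init__(self) -> None:
        if not MIN_K <= self.k <= MAX_K:
            raise ValueError(f"k must be in [{MIN_K}, {MAX_K}], got {self.k}")

    @property
    def size(self) -> int:
        return len(STANDARD_ALPHABET) ** self.k

    @cached_property
    def kmers(self) -> list[str]:
        return [
            "".join(t) for t in itertools.product(STANDARD_ALPHABET, repeat=self.k)
        ]

    def index(self, kmer: str) -> int:
        """Position of ``kmer`` in the lexicographic enumeration."""
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got {kmer!r}")
        idx = 0
        for ch in kmer:
            code = _CODE[ord(ch)] if ord(ch) < 128 else -1
            if code < 0:
                raise KeyError(f"non-standard residue in k-mer {kmer!r}")
            idx = idx * 20 + code
        return idx

    def kmer_at(self, index: int) -> str:
        if not 0 <= index < self.size:
            raise IndexError(index)
        out = []
        for _ in range(self.k):
            index, r = divmod(index, 20)
            out.append(STANDARD_ALPHABET[r])
        return "".join(reversed(out))


def build_vocabulary(k: int) -> KmerVocabulary:
    """Complete deterministic k-mer vocabulary for window length ``k`` (1-5)."""
    return KmerVocabulary(k=k)


@dataclass
class FeatureMatrix:
    """Relative k-mer frequency matrix: rows = sequences, columns = features.

    ``columns`` holds the vocabulary index of each column (the identity
    arangement when unmasked).
    """

    values: np.ndarray | sp.csr_matrix
    row_ids: list[str]
    k: int
    masked: bool = False
    columns: np.ndarray | None = field(default=None)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return self.values


def _window_indices(sequence: str, k: int) -> np.ndarray:
    """Vocabulary indices of all valid length-k windows of ``sequence``."""
    codes = _CODE[np.frombuffer(sequence.encode("ascii", "replace"), dtype=np.uint8)]
    n_win = len(codes) - k + 1
    if n_win <= 0:
        return np.empty(0, dtype=np.int64)
    # Base-20 positional encoding of each window; windows touching an invalid
    # residue (code -1) are discarded.
    idx = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    for j in range(k):
        c = codes[j : j + n_win]
        valid &= c >= 0
        idx = idx * 20 + c
    return idx[valid]


def kmer_frequencies(sequence: str, vocab: KmerVocabulary) -> np.ndarray:
    """Relative k-mer frequency vector of one sequence over the full vocabulary.

    Returns an all-zero vector (with a warning) when the sequence has no valid
    window, e.g. when it is shorter than k.
    """
    freq = np.zeros(vocab.size, dtype=np.float64)
    win = _window_indices(sequence, vocab.k)
    if win.size == 0:
        if len(sequence) < vocab.k:
            warnings.warn("sequence shorter than k; zero feature vector", stacklevel=2)
        else:
            warnings.warn("sequence has no valid k-mer window", stacklevel=2)
        return freq
    counts = np.bincount(win, minlength=vocab.size)
    np.divide(counts, win.size, out=freq)
    return freq


def encode_corpus(
    corpus: LabeledCorpus | Sequence[ProteinRecord], vocab: KmerVocabulary
) -> FeatureMatrix:
    """Encode every record of ``corpus`` (one row each, in order).

    Dense float64 for k<=3; CSR sparse for k in {4, 5}.
    """
    records = list(corpus)
    if not records:
        raise ValueError("cannot encode an empty corpus")
    row_ids = [r.id for r in records]
    if vocab.k <= _DENSE_K_MAX:
        values = np.zeros((len(records), vocab.size), dtype=np.float64)
        for i, rec in enumerate(records):
            win = _window_indices(rec.sequence, vocab.k)
            if win.size:
                values[i] = np.bincount(win, minlength=vocab.size) / win.size
            else:
                logger.warning("record %s: no valid %d-mer window", rec.id, vocab.k)
        return FeatureMatrix(values=values, row_ids=row_ids, k=vocab.k)

    data: list[np.ndarray] = []
    indices: list[np.ndarray] = []
    indptr = [0]
    for rec in records:
        win = _window_indices(rec.sequence, vocab.k)
        if win.size:
            cols, counts = np.unique(win, return_counts=True)
            data.append(counts / win.size)
            indices.append(cols)
        else:
            logger.warning("record %s: no valid %d-mer window", rec.id, vocab.k)
        indptr.append(indptr[-1] + (win.size and len(indices[-1]) or 0))
    values = sp.csr_matrix(
        (
            np.concatenate(data) if data else np.empty(0),
            np.concatenate(indices) if indices else np.empty(0, dtype=np.int64),
            np.asarray(indptr),
        ),
        shape=(len(records), vocab.size),
    )
    return FeatureMatrix(values=values, row_ids=row_ids, k=vocab.k)


def apply_mask(matrix: FeatureMatrix, mask) -> FeatureMatrix:
    """Restrict a full-vocabulary matrix to the mask's columns, in mask order.

    The result is dense (masked widths are small by construction). Row sums
    are no longer guaranteed to be 1.
    """
    if matrix.masked:
        raise ValueError("matrix is already masked")
    if mask.k != matrix.k:
        raise ValueError(f"mask k={mask.k} does not match matrix k={matrix.k}")
    idx = np.asarray(mask.indices, dtype=np.int64)
    if idx.size and (idx.min() < 0 or idx.max() >= matrix.shape[1]):
        raise IndexError("mask index out of range for matrix")
    sub = matrix.values[:, idx]
    if sp.issparse(sub):
        sub = np.asarray(sub.todense())
    return FeatureMatrix(
        values=np.ascontiguousarray(sub),
        row_ids=list(matrix.row_ids),
        k=matrix.k,
        masked=True,
        columns=idx.copy(),
    )
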