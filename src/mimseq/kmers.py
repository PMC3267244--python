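"""Canonical k-mer indexing, counting and pooled distributions.

A DNA k-mer and its reverse complement read out the same double-stranded
word, so they are collapsed into one *canonical* k-mer — the
lexicographically smaller of the pair.  For k = 4 the 256 words collapse
into 136 canonical classes (120 complement pairs plus 16 palindromes).

Counting slides a width-k window with step 1 over each sequence; windows
containing ``N`` are skipped; each valid window increments exactly one
canonical bin, so row sums equal valid-window counts and the resulting
profile is invariant under reverse complementation of the input.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import SequenceSet

_BASES = "ACGT"
# byte value -> base code; 4 encodes N / anything else
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _ENCODE[_b] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(sequence: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A,C,G,T -> 0..3, N -> 4)."""
    return _ENCODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _DECODE[codes].tobytes().decode("ascii")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def canonical_kmer(word: str) -> str:
    """Return the canonical representative of ``word``: the lexicographically
    smaller of the word and its reverse complement.

    Raises ``ValueError`` for words containing characters outside ``ACGT``.
    """
    if not word or set(word) - set(_BASES):
        raise ValueError(f"k-mer must be non-empty over ACGT, got {word!r}")
    rc = reverse_complement(word)
    return min(word, rc)


def _revcomp_codes(k: int) -> np.ndarray:
    """Integer code of the reverse complement for every k-mer code 0..4^k-1."""
    codes = np.arange(4**k, dtype=np.int64)
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - tmp % 4)
        tmp //= 4
    return rc


def _code_to_word(code: int, k: int) -> str:
    letters = []
    for _ in range(k):
        letters.append(_BASES[code % 4])
        code //= 4
    return "".join(reversed(letters))


@dataclass(frozen=True)
class KmerIndex:
    """Index of canonical k-mers: canonical words in lexicographic order and
    a fold table from any of the 4^k integer word codes to a canonical bin."""

    k: int
    kmers: tuple[str, ...]
    fold: np.ndarray  # shape (4^k,), word code -> canonical bin

    @property
    def size(self) -> int:
        return len(self.kmers)

    def lookup(self, word: str) -> int:
        """Canonical bin of an arbitrary k-mer over ACGT."""
        if len(word) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got {word!r}")
        codes = encode(word)
        if (codes > 3).any():
            raise ValueError(f"k-mer contains non-ACGT characters: {word!r}")
        code = 0
        for c in codes:
            code = code * 4 + int(c)
        return int(self.fold[code])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, KmerIndex)
            and self.k == other.k
            and self.kmers == other.kmers
        )

    def __hash__(self) -> int:
        return hash((self.k, self.kmers))


@lru_cache(maxsize=8)
def enumerate_canonical_kmers(k: int = 4) -> KmerIndex:
    """Enumerate all reverse-complement equivalence classes of ACGT words of
    length k, ordered lexicographically by canonical representative.

    For k = 4 this yields 136 canonical k-mers.
    """
    if not isinstance(k, (int, np.integer)) or k <= 0:
        raise ValueError(f"k must be a positive integer, got {k!r}")
    rc = _revcomp_codes(k)
    codes = np.arange(4**k, dtype=np.int64)
    canon = np.minimum(codes, rc)
    unique = np.unique(canon)  # sorted; code order == lexicographic order
    fold = np.searchsorted(unique, canon).astype(np.int64)
    kmers = tuple(_code_to_word(int(c), k) for c in unique)
    return KmerIndex(k=k, kmers=kmers, fold=fold)


@dataclass(frozen=True)
class FrequencyMatrix:
    """Per-sequence canonical k-mer counts: row i holds the counts of
    sequence i over the canonical bins, summing to its valid-window count."""

    index: KmerIndex
    counts: np.ndarray  # (n, m) int64
    valid_windows: np.ndarray  # (n,) int64

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    def relative(self) -> np.ndarray:
        """Rows as relative frequencies; all-zero rows stay zero."""
        denom = np.where(self.valid_windows > 0, self.valid_windows, 1)
        return self.counts / denom[:, None]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.counts, columns=list(self.index.kmers))


@dataclass(frozen=True)
class AggregateDistribution:
    """Pooled canonical k-mer probabilities of a sequence set, optionally
    smoothed with a per-bin pseudocount."""

    index: KmerIndex
    probs: np.ndarray  # (m,)
    pseudocount: float

    def __post_init__(self) -> None:
        if abs(float(self.probs.sum()) - 1.0) > 1e-12:
            raise ValueError("aggregate probabilities must sum to 1")


@dataclass(frozen=True)
class PerKmerStats:
    """Per-k-mer mean and variance of per-sequence relative frequencies.

    ``variances`` uses the unbiased (n-1) normalization.
    """

    index: KmerIndex
    means: np.ndarray
    variances: np.ndarray


def _count_codes(a: np.ndarray, index: KmerIndex) -> tuple[np.ndarray, int]:
    """Count canonical k-mers in one encoded sequence array."""
    k, m = index.k, index.size
    L = a.shape[0]
    if L < k:
        return np.zeros(m, dtype=np.int64), 0
    W = L - k + 1
    isn = (a > 3).astype(np.int64)
    if isn.any():
        # window invalid iff it covers at least one N
        cs = np.concatenate(([0], np.cumsum(isn)))
        valid = (cs[k:] - cs[:-k]) == 0
    else:
        valid = None
    aa = np.where(a > 3, 0, a).astype(np.int64)
    codes = np.zeros(W, dtype=np.int64)
    for i in range(k):
        codes = codes * 4 + aa[i : i + W]
    if valid is not None:
        codes = codes[valid]
    counts = np.bincount(index.fold[codes], minlength=m)
    return counts.astype(np.int64), codes.shape[0]


def count_kmers(sequence: str, index: KmerIndex) -> tuple[np.ndarray, int]:
    """Count canonical k-mers in a single sequence.

    Returns ``(counts, n_valid_windows)``.  Sequences shorter than k yield
    all-zero counts; windows containing N are skipped.
    """
    return _count_codes(encode(sequence), index)


def _profile_equal_length(seqs: list[str], index: KmerIndex) -> FrequencyMatrix:
    """Vectorized profiling when all sequences share one length (the common
    case for simulated and null sets)."""
    k, m = index.k, index.size
    n = len(seqs)
    L = len(seqs[0])
    A = _ENCODE[
        np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    ].reshape(n, L)
    if L < k:
        return FrequencyMatrix(index, np.zeros((n, m), np.int64), np.zeros(n, np.int64))
    W = L - k + 1
    AA = np.where(A > 3, 0, A).astype(np.int64)
    codes = np.zeros((n, W), dtype=np.int64)
    for i in range(k):
        codes = codes * 4 + AA[:, i : i + W]
    bins = index.fold[codes]
    if (A > 3).any():
        isn = (A > 3).astype(np.int64)
        cs = np.concatenate([np.zeros((n, 1), np.int64), np.cumsum(isn, axis=1)], axis=1)
        valid = (cs[:, k:] - cs[:, :-k]) == 0
    else:
        valid = np.ones((n, W), dtype=bool)
    flat = (bins + np.arange(n, dtype=np.int64)[:, None] * m)[valid]
    counts = np.bincount(flat, minlength=n * m).reshape(n, m)
    return FrequencyMatrix(index, counts.astype(np.int64), valid.sum(axis=1).astype(np.int64))


def profile_set(seq_set: SequenceSet | list[str], index: KmerIndex) -> FrequencyMatrix:
    """Profile a sequence set into an n x m canonical k-mer count matrix."""
    seqs = seq_set.sequences if isinstance(seq_set, SequenceSet) else list(seq_set)
    if not seqs:
        raise ValueError("cannot profile an empty sequence set")
    lengths = {len(s) for s in seqs}
    if len(lengths) == 1 and lengths != {0}:
        return _profile_equal_length(seqs, index)
    m = index.size
    counts = np.zeros((len(seqs), m), dtype=np.int64)
    windows = np.zeros(len(seqs), dtype=np.int64)
    for i, s in enumerate(seqs):
        counts[i], windows[i] = count_kmers(s, index)
    return FrequencyMatrix(index, counts, windows)


def aggregate_distribution(
    matrix: FrequencyMatrix, pseudocount: float = 1.0
) -> AggregateDistribution:
    """Pool a count matrix into one probability vector:
    ``p_j = (sum_i c_ij + a) / (sum_ij c_ij + m a)`` with pseudocount ``a``."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    total = matrix.counts.sum(axis=0).astype(float) + pseudocount
    denom = total.sum()
    if denom <= 0:
        raise ValueError("all-zero count matrix with zero pseudocount")
    return AggregateDistribution(matrix.index, total / denom, pseudocount)


def per_sequence_stats(matrix: FrequencyMatrix) -> PerKmerStats:
    """Mean and unbiased variance, per canonical k-mer, of the per-sequence
    relative frequencies.  Requires at least two sequences."""
    if matrix.n < 2:
        raise ValueError("per-sequence statistics need at least 2 sequences")
    rel = matrix.relative()
    means = rel.mean(axis=0)
    variances = rel.var(axis=0, ddof=1)
    return PerKmerStats(matrix.index, means, variances)


class KmerCounter(TransformerMixin, BaseEstimator):
    """Transform DNA sequences into canonical k-mer count vectors.

    A scikit-learn transformer: ``transform`` maps a list of sequence strings
    (or a :class:`~mimseq.io.SequenceSet`) to an ``(n, m)`` count matrix over
    the canonical k-mers, suitable for use in sklearn pipelines.

    Parameters
    ----------
    k : int, default 4
        Word length.  k = 4 gives 136 canonical k-mers.

    Attributes
    ----------
    index_ : KmerIndex
        The canonical k-mer index, set by :meth:`fit`.
    """

    def __init__(self, k: int = 4):
        self.k = k

    def fit(self, X=None, y=None):
        self.index_ = enumerate_canonical_kmers(self.k)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "index_"):
            self.fit()
        return profile_set(X, self.index_).counts

    def get_feature_names_out(self, input_features=None):
        if not hasattr(self, "index_"):
            self.fit()
        return np.asarray(self.index_.kmers, dtype=object)
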