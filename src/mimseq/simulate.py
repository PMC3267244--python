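"""Synthetic ChIP-seq benchmark generator.

Emulates a transcription-factor ChIP-seq experiment whose factor binds a
single 6 bp motif (consensus TTGACA by default).  Background sequences are
drawn i.i.d. from a fixed base distribution (A,C,G,T = 0.15, 0.35, 0.35,
0.15 by default — a GC-rich composition typical of regulatory regions); a
random subset of sequences then receives one motif instance sampled from a
position weight matrix parameterized by a mutation rate epsilon:

* each column places probability ``1 - 3*epsilon`` on the consensus base
  and ``epsilon`` on the other three;
* epsilon = 0 is a perfect motif, epsilon = 0.25 a fully random one.

The defaults — 2000 sequences of 500 bp with the motif implanted into 1000
of them — define the benchmark conditions; the implant overwrites the
sampled bases at a uniformly chosen offset so sequence length is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SequenceSet
from .kmers import decode

_BASES = "ACGT"
_BASE_TO_IDX = {b: i for i, b in enumerate(_BASES)}

DEFAULT_CONSENSUS = "TTGACA"
DEFAULT_BACKGROUND = (0.15, 0.35, 0.35, 0.15)


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: per-position base probabilities of a motif.

    ``probs`` has shape (width, 4) with columns in A, C, G, T order; every
    row sums to 1.
    """

    consensus: str
    epsilon: float
    probs: np.ndarray

    @property
    def width(self) -> int:
        return len(self.consensus)

    def __post_init__(self) -> None:
        if self.probs.shape != (self.width, 4):
            raise ValueError("PWM probs must have shape (width, 4)")
        if not np.allclose(self.probs.sum(axis=1), 1.0):
            raise ValueError("PWM rows must sum to 1")


def build_pwm(consensus: str = DEFAULT_CONSENSUS, epsilon: float = 0.0) -> PWM:
    """Build the mutation-rate PWM: probability ``1 - 3*epsilon`` on the
    consensus base of each position, ``epsilon`` on each other base."""
    if not (0.0 <= epsilon <= 0.25):
        raise ValueError(f"epsilon must be in [0, 0.25], got {epsilon}")
    if not consensus or set(consensus) - set(_BASES):
        raise ValueError(f"consensus must be non-empty over ACGT, got {consensus!r}")
    probs = np.full((len(consensus), 4), epsilon, dtype=float)
    for i, base in enumerate(consensus):
        probs[i, _BASE_TO_IDX[base]] = 1.0 - 3.0 * epsilon
    return PWM(consensus=consensus, epsilon=epsilon, probs=probs)


def sample_motif_instance(pwm: PWM, rng: np.random.Generator) -> str:
    """Draw one motif word, each position independently from its column."""
    return decode(_sample_instances(pwm, 1, rng)[0])


def _sample_instances(pwm: PWM, n: int, rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(pwm.probs, axis=1)
    u = rng.random((n, pwm.width))
    codes = (u[:, :, None] > cum[None, :, :-1]).sum(axis=2)
    return codes.astype(np.uint8)


def information_content(
    pwm: PWM, background: tuple[float, float, float, float] = DEFAULT_BACKGROUND
) -> float:
    """Relative entropy of the PWM to the background base distribution, in
    bits, summed over positions (convention 0*log 0 = 0)."""
    q = np.asarray(background, dtype=float)
    used = pwm.probs.sum(axis=0) > 0
    if (q[used] <= 0).any():
        raise ValueError("background assigns zero probability to a base the PWM uses")
    p = pwm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / q[None, :]), 0.0)
    return float(terms.sum())


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Defaults are the benchmark conditions: 2000 sequences of 500 bp over
    background (0.15, 0.35, 0.35, 0.15), one TTGACA-motif instance implanted
    into 1000 randomly chosen sequences.
    """

    epsilon: float
    n_sequences: int = 2000
    length: int = 500
    n_implant: int = 1000
    background_probs: tuple[float, float, float, float] = DEFAULT_BACKGROUND
    consensus: str = DEFAULT_CONSENSUS
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.epsilon <= 0.25):
            raise ValueError(f"epsilon must be in [0, 0.25], got {self.epsilon}")
        if self.n_implant > self.n_sequences:
            raise ValueError("n_implant cannot exceed n_sequences")
        if self.length < len(self.consensus):
            raise ValueError("sequence length must be at least the motif width")
        probs = np.asarray(self.background_probs, dtype=float)
        if probs.shape != (4,) or (probs < 0).any() or abs(probs.sum() - 1) > 1e-9:
            raise ValueError("background_probs must be 4 non-negative values summing to 1")


def generate_dataset(spec: SyntheticSpec) -> tuple[SequenceSet, pd.DataFrame]:
    """Generate one synthetic ChIP-seq dataset.

    Returns the sequence set and an implant log with one row per implanted
    sequence: ``sequence_id``, ``offset`` (0-based start of the motif) and
    ``word`` (the implanted instance).  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    pwm = build_pwm(spec.consensus, spec.epsilon)
    n, L, w = spec.n_sequences, spec.length, pwm.width
    cum = np.cumsum(np.asarray(spec.background_probs, dtype=float))
    codes = np.searchsorted(cum, rng.random((n, L)), side="right").astype(np.uint8)
    chosen = np.sort(rng.choice(n, size=spec.n_implant, replace=False))
    offsets = rng.integers(0, L - w + 1, size=spec.n_implant)
    words = _sample_instances(pwm, spec.n_implant, rng)
    for row, (i, off) in enumerate(zip(chosen, offsets)):
        codes[i, off : off + w] = words[row]
    ids = [f"seq_{i:05d}" for i in range(n)]
    records = tuple((ids[i], decode(codes[i])) for i in range(n))
    log = pd.DataFrame(
        {
            "sequence_id": [ids[i] for i in chosen],
            "offset": offsets.astype(int),
            "word": [decode(wd) for wd in words],
        }
    )
    return SequenceSet(records), log
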