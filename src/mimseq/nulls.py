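"""Random-sequence null models.

A null set matches the target set in the number of sequences and in every
per-sequence length; only the sequence content is randomized.  Three
generators are available:

* ``background`` — i.i.d. letters from fixed base probabilities (the
  synthetic-benchmark null; the default probabilities are uniform, the
  simulated ChIP-seq experiments use 0.15/0.35/0.35/0.15 for A/C/G/T);
* ``shuffle`` — each target sequence's letters are permuted uniformly
  (mononucleotide shuffle: per-sequence base composition is preserved);
* ``genome`` — length-matched intervals sampled from a reference genome,
  contigs weighted by length, rejecting intervals with more than 10% N.

Replicate b of a run draws from an independent RNG stream derived from
(seed, b), so results are reproducible and extending B leaves earlier
replicates unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import SequenceSet
from .kmers import decode, encode

GENERATORS = ("background", "shuffle", "genome")

UNIFORM_PROBS = (0.25, 0.25, 0.25, 0.25)
#: background of the synthetic ChIP-seq benchmark (A, C, G, T)
SYNTHETIC_PROBS = (0.15, 0.35, 0.35, 0.15)

_MAX_N_FRACTION = 0.10
_MAX_REJECTS = 1000


@dataclass(frozen=True)
class NullSpec:
    """Configuration of the null model.

    Parameters
    ----------
    generator : {"background", "shuffle", "genome"}
    background_probs : probabilities of A, C, G, T (background generator only)
    B : number of null replicate sets (default 1000)
    seed : master RNG seed
    genome_path : genome FASTA, required for the genome generator
    """

    generator: str = "background"
    background_probs: tuple[float, float, float, float] = UNIFORM_PROBS
    B: int = 1000
    seed: int = 0
    genome_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.generator not in GENERATORS:
            raise ValueError(
                f"unknown null generator {self.generator!r}; expected one of {GENERATORS}"
            )
        probs = np.asarray(self.background_probs, dtype=float)
        if probs.shape != (4,) or (probs < 0).any() or abs(probs.sum() - 1) > 1e-9:
            raise ValueError("background_probs must be 4 non-negative values summing to 1")
        if self.B < 2:
            raise ValueError("B must be at least 2")
        if self.generator == "genome" and not self.genome_path:
            raise ValueError("genome generator requires genome_path")


def _rng_for(spec: NullSpec, replicate: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(replicate,))
    )


def _sample_background(
    lengths: list[int], probs: np.ndarray, rng: np.random.Generator
) -> list[str]:
    cum = np.cumsum(probs)
    total = int(sum(lengths))
    codes = np.searchsorted(cum, rng.random(total), side="right").astype(np.uint8)
    out, pos = [], 0
    for L in lengths:
        out.append(decode(codes[pos : pos + L]))
        pos += L
    return out


def _shuffle_sequences(seqs: list[str], rng: np.random.Generator) -> list[str]:
    return [decode(rng.permutation(encode(s))) for s in seqs]


def _sample_genome(
    lengths: list[int], genome_path: str, rng: np.random.Generator
) -> list[str]:
    from pyfaidx import Fasta

    genome = Fasta(genome_path, as_raw=True, sequence_always_upper=True)
    names = list(genome.keys())
    contig_lens = np.array([len(genome[c]) for c in names], dtype=np.int64)
    longest = max(lengths)
    if contig_lens.max() < longest:
        raise ValueError(
            f"no contig is long enough for a {longest} bp interval "
            f"(longest contig: {contig_lens.max()} bp)"
        )
    out = []
    for L in lengths:
        ok = contig_lens >= L
        weights = np.where(ok, contig_lens, 0).astype(float)
        weights /= weights.sum()
        for _ in range(_MAX_REJECTS):
            ci = int(rng.choice(len(names), p=weights))
            start = int(rng.integers(0, contig_lens[ci] - L + 1))
            seq = genome[names[ci]][start : start + L]
            if seq.count("N") <= _MAX_N_FRACTION * L:
                out.append(seq)
                break
        else:
            raise RuntimeError(
                f"could not draw a {L} bp interval with <=10% N after "
                f"{_MAX_REJECTS} attempts"
            )
    return out


def generate_null_set(
    template: SequenceSet, spec: NullSpec, replicate: int = 0
) -> SequenceSet:
    """Generate one null replicate matching the template's n and lengths.

    Deterministic given ``(spec.seed, replicate)``.
    """
    rng = _rng_for(spec, replicate)
    lengths = template.lengths
    if spec.generator == "background":
        seqs = _sample_background(
            lengths, np.asarray(spec.background_probs, dtype=float), rng
        )
    elif spec.generator == "shuffle":
        seqs = _shuffle_sequences(template.sequences, rng)
    else:
        seqs = _sample_genome(lengths, spec.genome_path, rng)
    ids = tuple(f"null{replicate}_{i}" for i in range(len(seqs)))
    return SequenceSet(tuple(zip(ids, seqs)))
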