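"""Reading, writing and extracting DNA sequence sets.

The unit of analysis throughout the package is a :class:`SequenceSet`:
an ordered collection of named DNA sequences over the alphabet
``{A, C, G, T, N}``.  Sequences are normalized to upper case on input and
any IUPAC ambiguity code outside ``ACGT`` is collapsed to ``N`` (masked
genomic bases carry no composition signal and are skipped by the k-mer
counter).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

_VALID = frozenset("ACGTN")
# every printable character that is not ACGT becomes N
_AMBIG_TABLE = {ord(c): "N" for c in
                "BDEFHIJKLMOPQRSUVWXYZ" + "bdefhijklmopqrsuvwxyz" + "-.*"}
_UPPER_TABLE = {ord(c): c.upper() for c in "acgtn"}


@dataclass(frozen=True)
class SequenceSet:
    """An ordered set of named DNA sequences over ``{A,C,G,T,N}``.

    Parameters
    ----------
    records
        Ordered ``(identifier, sequence)`` pairs.  Sequences must already be
        upper-case over the five-letter alphabet; use :meth:`from_raw` to
        normalize arbitrary input.
    """

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        for ident, seq in self.records:
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(
                    f"record {ident!r} contains invalid characters {sorted(bad)}; "
                    "use SequenceSet.from_raw to normalize"
                )

    @classmethod
    def from_raw(cls, pairs: Iterable[tuple[str, str]]) -> "SequenceSet":
        """Build a set from raw pairs, upper-casing and mapping ambiguity
        codes to ``N``.  Logs the total number of replaced characters."""
        records = []
        n_replaced = 0
        for ident, seq in pairs:
            norm = seq.translate(_UPPER_TABLE).translate(_AMBIG_TABLE)
            n_replaced += sum(1 for a, b in zip(seq.upper(), norm) if a != b)
            records.append((ident, norm))
        if n_replaced:
            logger.warning(
                "%d non-ACGT characters replaced with N during normalization",
                n_replaced,
            )
        return cls(tuple(records))

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [ident for ident, _ in self.records]

    @property
    def sequences(self) -> list[str]:
        return [seq for _, seq in self.records]

    @property
    def lengths(self) -> list[int]:
        return [len(seq) for _, seq in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.records)


def read_fasta(path: str | PathLike) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Lower-case (soft-masked) letters are upper-cased and ambiguity codes
    become ``N`` (one warning logs the total count).  Raises ``ValueError``
    on an empty file or on sequence data appearing before the first header
    (the error names the offending line).
    """
    path = Path(path)
    # pre-scan: locate sequence data before any header for a line-numbered error
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno}: sequence data before first FASTA header"
                )
            break
        else:
            raise ValueError(f"{path}: empty FASTA file")
    pairs = ((rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta"))
    result = SequenceSet.from_raw(pairs)
    if result.n == 0:
        raise ValueError(f"{path}: no FASTA records found")
    return result


def write_fasta(seq_set: SequenceSet, path: str | PathLike) -> None:
    """Write a :class:`SequenceSet` as FASTA with 60-column line wrapping."""
    if seq_set.n == 0:
        raise ValueError("cannot write an empty SequenceSet")
    records = (
        SeqRecord(Seq(seq), id=ident, description="") for ident, seq in seq_set
    )
    SeqIO.write(records, str(path), "fasta")


def extract_bed_intervals(
    bed_path: str | PathLike, genome_path: str | PathLike
) -> SequenceSet:
    """Extract reference-strand sequences for BED intervals from a genome FASTA.

    Coordinates follow the standard BED dialect: 0-based, half-open.  A strand
    column, if present, is ignored — downstream canonical k-mer counting is
    strand-symmetric, so the forward reference sequence carries the same
    information.  Record identifiers are ``chrom:start-end``.
    """
    genome = Fasta(str(genome_path), as_raw=True, sequence_always_upper=True)
    pairs: list[tuple[str, str]] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            fields = stripped.split("\t") if "\t" in stripped else stripped.split()
            if len(fields) < 3:
                raise ValueError(f"{bed_path}: line {lineno}: fewer than 3 BED columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(
                    f"{bed_path}: line {lineno}: non-integer coordinates"
                ) from exc
            if chrom not in genome:
                raise ValueError(f"{bed_path}: line {lineno}: unknown chromosome {chrom!r}")
            contig_len = len(genome[chrom])
            if start < 0 or end > contig_len or start >= end:
                raise ValueError(
                    f"{bed_path}: line {lineno}: interval {chrom}:{start}-{end} "
                    f"outside contig of length {contig_len}"
                )
            pairs.append((f"{chrom}:{start}-{end}", genome[chrom][start:end]))
    if not pairs:
        raise ValueError(f"{bed_path}: no intervals found")
    return SequenceSet.from_raw(pairs)
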