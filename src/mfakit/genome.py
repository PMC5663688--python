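"""Circular reference genomes and sequence utilities.

A :class:`GenomeRecord` is a single circular (or linear) replicon held as an
upper-case DNA string plus numpy helpers (base codes, GC prefix sums) that the
windowing and simulation code lean on.  Coordinates are 0-based, half-open
everywhere; circular wrap-around is always expressed by splitting an interval
at ``L``, never by coordinates ``>= L``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_ALLOWED = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceAlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,N}."""


@dataclass
class GenomeRecord:
    """A single replicon.

    Parameters
    ----------
    id : str
        Sequence identifier (FASTA header word).
    sequence : str
        Upper-case DNA.  ``N`` is tolerated: it counts as neither G nor C but
        still occupies a position.
    circular : bool
        Whether coordinates wrap at ``len(sequence)``.
    """

    id: str
    sequence: str
    circular: bool = True
    _gc_mask: np.ndarray = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise SequenceAlphabetError(
                f"genome {self.id!r} contains non-ACGTN characters: {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc_mask(self) -> np.ndarray:
        """Boolean array, True at G/C positions."""
        if self._gc_mask is None:
            arr = np.frombuffer(self.sequence.encode("ascii"), dtype=np.uint8)
            self._gc_mask = (arr == ord("G")) | (arr == ord("C"))
        return self._gc_mask

    def gc_prefix(self) -> np.ndarray:
        """Length ``L + 1`` prefix-sum of the GC mask (prefix[i] = #GC in [0, i))."""
        return np.concatenate([[0], np.cumsum(self.gc_mask)])

    def fetch(self, start: int, end: int) -> str:
        """Sequence of ``[start, end)``; wraps past ``L`` on circular genomes."""
        L = self.length
        if not 0 <= start < L or not start < end:
            raise ValueError(f"bad interval [{start}, {end}) on genome of length {L}")
        if end <= L:
            return self.sequence[start:end]
        if not self.circular or end - start > L:
            raise ValueError(f"interval [{start}, {end}) exceeds linear genome {L}")
        return self.sequence[start:] + self.sequence[: end - L]

    def gc_fraction(self, start: int, end: int) -> float:
        seq = self.fetch(start, end)
        return (seq.count("G") + seq.count("C")) / (end - start)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def circular_distance(a: int, b: int, L: int) -> int:
    """Shortest distance between positions a and b on a circle of size L."""
    d = abs(a - b) % L
    return min(d, L - d)


def read_fasta(path, circular: bool = True) -> GenomeRecord:
    """Read the first (single) record of a FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if len(records) > 1:
        raise ValueError(
            f"{path} holds {len(records)} records; expected a single replicon"
        )
    rec = records[0]
    return GenomeRecord(id=rec.id, sequence=str(rec.seq).upper(), circular=circular)


def write_fasta(genome: GenomeRecord, path, width: int = 70) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, description="")
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "fasta-2line" if width == 0 else "fasta")
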