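"""IUPAC nucleotide sequences, reverse complement, palindromes, degenerate matching.

Every other module works on :class:`NucleotideSequence`, a thin validated
wrapper around an upper-case IUPAC string.  DNA palindromes — sequences equal
to their own reverse complement, such as restriction-enzyme recognition sites
— are the anchors of the whole PST-PCR scheme, so palindrome testing and
degenerate-code matching live here.

Coordinates are 0-based half-open throughout the library; writers that face
humans (BED is already 0-based) convert where a format demands 1-based.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterator

from Bio import SeqIO

__all__ = [
    "IUPAC_CODES",
    "AMBIGUITY",
    "NucleotideSequence",
    "GenomicInterval",
    "reverse_complement",
    "is_palindrome",
    "matches",
    "read_fasta",
    "write_fasta",
]

#: allowed set for each IUPAC ambiguity code
AMBIGUITY: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_CODES = frozenset(AMBIGUITY)

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)


class SequenceError(ValueError):
    """Invalid residue or malformed sequence input."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A validated IUPAC DNA string.

    Input is case-insensitive; ``U`` is converted to ``T`` on ingest (primer
    catalogs occasionally derive from mRNA references).  The empty sequence
    is permitted only as a neutral element for concatenation.
    """

    residues: str
    name: str = ""

    def __post_init__(self) -> None:
        canon = self.residues.upper().replace("U", "T")
        for i, ch in enumerate(canon):
            if ch not in IUPAC_CODES:
                raise SequenceError(
                    f"invalid IUPAC residue {ch!r} at position {i}"
                    + (f" in {self.name!r}" if self.name else "")
                )
        object.__setattr__(self, "residues", canon)

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def __getitem__(self, key) -> "NucleotideSequence":
        return NucleotideSequence(self.residues[key], self.name)

    def __add__(self, other: "NucleotideSequence") -> "NucleotideSequence":
        return NucleotideSequence(self.residues + other.residues)

    @property
    def is_unambiguous(self) -> bool:
        return all(ch in "ACGT" for ch in self.residues)


def _as_str(seq) -> str:
    return seq.residues if isinstance(seq, NucleotideSequence) else str(seq)


def reverse_complement(seq) -> NucleotideSequence:
    """IUPAC-aware reverse complement (R<->Y, S<->S, B<->V, N<->N, ...).

    An involution: applying it twice returns the input.
    """
    s = seq if isinstance(seq, NucleotideSequence) else NucleotideSequence(str(seq))
    return NucleotideSequence(s.residues.translate(_COMPLEMENT)[::-1], s.name)


def is_palindrome(seq) -> bool:
    """True iff *seq* equals its own reverse complement.

    Defined only for unambiguous sequences: restriction sites are concrete
    motifs, so degenerate residues raise rather than guess.
    Odd-length strings can never be palindromic under base-pairing.
    """
    s = seq if isinstance(seq, NucleotideSequence) else NucleotideSequence(str(seq))
    if not s.is_unambiguous:
        raise SequenceError(f"palindromy is undefined for degenerate sequence {s.residues!r}")
    if len(s) % 2:
        return False
    return s.residues == reverse_complement(s).residues


def matches(pattern, target) -> bool:
    """Degenerate-aware equality: does the unambiguous *target* realize *pattern*?

    ``N`` matches any base, ``S`` matches G/C, and so on.  Lengths must agree.
    """
    p = _as_str(pattern)
    t = _as_str(target)
    if len(p) != len(t):
        raise SequenceError(f"length mismatch: pattern {len(p)} vs target {len(t)}")
    return all(tb in AMBIGUITY[pb] for pb, tb in zip(p, t))


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open 0-based interval on a named sequence.

    Strand ``"."`` marks strand-symmetric features (palindromic sites look
    identical on either strand).
    """

    sequence_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.sequence_id == other.sequence_id
            and self.start <= other.start
            and other.end <= self.end
        )


def read_fasta(path) -> list[NucleotideSequence]:
    """Read a multi-record FASTA file (wrapped or single-line, CRLF tolerated).

    Record names are the first whitespace-delimited token of each header.
    """
    records = []
    with open(os.fspath(path), "r", newline=None) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            records.append(NucleotideSequence(str(rec.seq), rec.id))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    return records


def write_fasta(seqs, path, width: int = 70) -> None:
    """Write sequences as wrapped FASTA."""
    with open(os.fspath(path), "w") as fh:
        for s in seqs:
            fh.write(f">{s.name or 'seq'}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")
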