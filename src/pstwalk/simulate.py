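"""Synthetic templates with exhaustive ground truth.

The generator emulates the walking scenario: an i.i.d. background at a
requested GC content, with primer annealing sites and palindromic PST sites
implanted at known coordinates.  Any background occurrence of an implanted
sequence (or its reverse complement) is destroyed by point resampling, so
the ground-truth table is *exhaustive*: a scanner must find the implants and
nothing else, allowing exact assertions instead of tolerances.

``generate_population`` additionally emulates fingerprinting across
accessions: each variant carries one random insertion or deletion between
the first two implants, so predicted product lengths differ across records
by exactly the implanted indel sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .sequences import AMBIGUITY, NucleotideSequence, reverse_complement, _as_str

__all__ = ["Implant", "FixtureSpec", "generate_genome", "generate_population", "realize"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Implant:
    feature: str
    sequence: str  # concrete A/C/G/T sequence written into the template
    position: int  # 0-based start on the plus strand
    strand: str = "+"

    @property
    def placed(self) -> str:
        return (
            self.sequence
            if self.strand == "+"
            else reverse_complement(NucleotideSequence(self.sequence)).residues
        )

    @property
    def end(self) -> int:
        return self.position + len(self.sequence)


@dataclass(frozen=True)
class FixtureSpec:
    length_bp: int
    gc_content: float
    seed: int
    implants: tuple[Implant, ...] = ()
    name: str = ""
    #: additional motifs whose background occurrences are destroyed even
    #: though they are not implanted (e.g. a whole primer-panel's palindromes)
    exclude_motifs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        spans = sorted((im.position, im.end) for im in self.implants)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping implants at {s1}-{e1} and {s2}-{e2}")
        for im in self.implants:
            if im.position < 0 or im.end > self.length_bp:
                raise ValueError(f"implant {im.feature!r} outside template bounds")
            if any(b not in "ACGT" for b in im.sequence):
                raise ValueError(f"implant {im.feature!r} must be a concrete A/C/G/T sequence")
            if self.gc_content == 0.0 and set(im.sequence) & {"G", "C"}:
                raise ValueError(f"implant {im.feature!r} needs G/C but gc_content is 0")
            if self.gc_content == 1.0 and set(im.sequence) & {"A", "T"}:
                raise ValueError(f"implant {im.feature!r} needs A/T but gc_content is 1")


def realize(seq, rng: np.random.Generator) -> str:
    """One concrete realization of a (possibly degenerate) IUPAC sequence."""
    return "".join(str(rng.choice(sorted(AMBIGUITY[c]))) for c in _as_str(seq))


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _find_all(hay: str, needle: str) -> list[int]:
    out, i = [], hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def _destroy_background(chars: list[str], implants: Sequence[Implant],
                        rng: np.random.Generator, gc: float,
                        exclude_motifs: Sequence[str] = (),
                        max_rounds: int = 1000) -> None:
    """Point-mutate away every off-implant occurrence of any implant sequence."""
    protected = set()
    for im in implants:
        protected.update(range(im.position, im.end))
    # occurrences of the placed text or its reverse complement both count
    patterns: dict[str, set[int]] = {}
    for im in implants:
        placed = im.placed
        rc = reverse_complement(NucleotideSequence(placed)).residues
        patterns.setdefault(placed, set()).add(im.position)
        patterns.setdefault(rc, set())
        if rc == placed:
            patterns[rc].add(im.position)
    for motif in exclude_motifs:
        patterns.setdefault(motif.upper(), set())
    probs = _base_probs(gc)
    for _ in range(max_rounds):
        dirty = False
        text = "".join(chars)
        for pat, allowed in patterns.items():
            for hit in _find_all(text, pat):
                if hit in allowed:
                    continue
                mutable = [i for i in range(hit, hit + len(pat)) if i not in protected]
                if not mutable:
                    raise ValueError(
                        f"spurious occurrence of {pat!r} inside an implant cannot be destroyed"
                    )
                pos = int(rng.choice(mutable))
                choices = [b for b in "ACGT" if b != chars[pos]]
                w = np.array([probs["ACGT".index(b)] for b in choices])
                if w.sum() == 0:
                    w = np.ones(len(choices))
                chars[pos] = str(rng.choice(choices, p=w / w.sum()))
                dirty = True
        if not dirty:
            return
    raise RuntimeError("background destruction did not converge")


def generate_genome(spec: FixtureSpec) -> tuple[NucleotideSequence, pd.DataFrame]:
    """Seeded i.i.d. template plus the exhaustive implant ground-truth table."""
    rng = np.random.default_rng(spec.seed)
    chars = list(rng.choice(_BASES, size=spec.length_bp, p=_base_probs(spec.gc_content)))
    chars = [str(c) for c in chars]
    for im in spec.implants:
        chars[im.position : im.end] = list(im.placed)
    if spec.implants or spec.exclude_motifs:
        _destroy_background(chars, spec.implants, rng, spec.gc_content, spec.exclude_motifs)
    name = spec.name or f"fixture_seed{spec.seed}"
    seq = NucleotideSequence("".join(chars), name)
    truth = pd.DataFrame(
        [
            {"feature": im.feature, "record": name, "start": im.position,
             "end": im.end, "strand": im.strand}
            for im in spec.implants
        ],
        columns=["feature", "record", "start", "end", "strand"],
    )
    return seq, truth


def generate_population(n: int, base_spec: FixtureSpec, indel_range: int,
                        ) -> tuple[list[NucleotideSequence], pd.DataFrame]:
    """*n* variants of the base template differing by one indel between the
    first two implants; product lengths across records differ by exactly the
    implanted indel sizes (recorded in the truth table's ``indel_bp``).
    """
    if n < 1:
        raise ValueError("need n >= 1")
    if len(base_spec.implants) < 2:
        raise ValueError("population fixtures need at least two implants")
    rng = np.random.default_rng(base_spec.seed)
    first, second = sorted(base_spec.implants, key=lambda im: im.position)[:2]
    gap_lo, gap_hi = first.end, second.position
    if gap_hi - gap_lo <= indel_range:
        raise ValueError("indel_range too large for the gap between implants")
    anchor = (gap_lo + gap_hi) // 2
    records: list[NucleotideSequence] = []
    truth_rows = []
    base_seq, _ = generate_genome(base_spec)
    for i in range(n):
        delta = int(rng.integers(-indel_range, indel_range + 1)) if indel_range else 0
        chars = list(base_seq.residues)
        if delta > 0:
            insert = [str(b) for b in rng.choice(_BASES, size=delta,
                                                 p=_base_probs(base_spec.gc_content))]
            chars[anchor:anchor] = insert
        elif delta < 0:
            del chars[anchor : anchor - delta]
        shifted = tuple(
            im if im.end <= anchor
            else Implant(im.feature, im.sequence, im.position + delta, im.strand)
            for im in base_spec.implants
        )
        name = f"{base_spec.name or 'var'}_{i}"
        _destroy_background(chars, shifted, rng, base_spec.gc_content, base_spec.exclude_motifs)
        records.append(NucleotideSequence("".join(chars), name))
        for im in shifted:
            truth_rows.append(
                {"feature": im.feature, "record": name, "start": im.position,
                 "end": im.end, "strand": im.strand, "indel_bp": delta}
            )
    return records, pd.DataFrame(truth_rows)
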