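"""Genome scanning for PST sites and inter-site spacing statistics.

A PST site is an exact occurrence of a palindromic motif (a 6- or 8-nt
restriction-enzyme recognition site).  Because a palindrome reads the same
on both strands, a single plus-strand pass finds every site; sites carry
strand ".".  The mean distance between successive sites divided by two is
the quick approximation of the arithmetic-mean length of walking products
anchored at that motif, and an i.i.d. base-composition model gives the
analytic counterpart (per-position hit probability p = prod of base
probabilities, mean spacing 1/p).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .sequences import NucleotideSequence, is_palindrome, read_fasta, _as_str

__all__ = [
    "PalindromeSiteSet",
    "SpacingStats",
    "scan_pst_sites",
    "spacing_stats",
    "analytic_spacing",
    "genome_report",
    "sites_to_bed",
]


@dataclass(frozen=True)
class PalindromeSiteSet:
    motif: str
    sequence_id: str
    positions: tuple[int, ...]  # sorted 0-based starts
    sequence_length: int

    @property
    def n_sites(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class SpacingStats:
    motif: str
    sequence_id: str
    n_sites: int
    sequence_length: Optional[int]
    mean_distance_bp: Optional[float]
    density_per_kb: Optional[float]
    expected_product_bp: Optional[float]  # always mean_distance_bp / 2


def scan_pst_sites(template, motif) -> PalindromeSiteSet:
    """All start positions of exact *motif* occurrences, overlaps included.

    The motif must be palindromic (so one strand suffices).  ``N`` runs in
    the template never match: assembly gaps must not create phantom sites.
    """
    m = _as_str(motif)
    if not is_palindrome(m):
        raise ValueError(f"{m!r} is not a palindrome")
    t = _as_str(template)
    positions = []
    i = t.find(m)
    while i != -1:
        positions.append(i)
        i = t.find(m, i + 1)  # overlapping occurrences count
    name = template.name if isinstance(template, NucleotideSequence) else ""
    return PalindromeSiteSet(m, name, tuple(positions), len(t))


def spacing_stats(sites: PalindromeSiteSet) -> SpacingStats:
    """Successive start-to-start gap statistics for one site set."""
    return _stats_from_gaps(
        sites.motif,
        sites.sequence_id,
        sites.n_sites,
        sites.sequence_length,
        np.diff(sites.positions) if sites.n_sites >= 2 else np.array([]),
    )


def _stats_from_gaps(motif, seq_id, n_sites, length, gaps) -> SpacingStats:
    mean = float(np.mean(gaps)) if len(gaps) else None
    return SpacingStats(
        motif=motif,
        sequence_id=seq_id,
        n_sites=n_sites,
        sequence_length=length,
        mean_distance_bp=mean,
        density_per_kb=1000.0 * n_sites / length if length else None,
        expected_product_bp=mean / 2.0 if mean is not None else None,
    )


def analytic_spacing(gc_content: float, motif) -> SpacingStats:
    """Expected spacing under an i.i.d. base model at the given GC content.

    P(G) = P(C) = gc/2 and P(A) = P(T) = (1-gc)/2; the per-position hit
    probability is the product over motif bases, and the mean inter-site
    distance its reciprocal.  A motif needing an absent base class (gc of
    0 or 1) has no finite spacing and all fields are reported absent.
    """
    if not 0.0 <= gc_content <= 1.0:
        raise ValueError("gc_content must be a fraction in [0, 1]")
    m = _as_str(motif)
    if not is_palindrome(m):
        raise ValueError(f"{m!r} is not a palindrome")
    p = 1.0
    for base in m:
        p *= gc_content / 2.0 if base in "GC" else (1.0 - gc_content) / 2.0
    if p == 0.0:
        return SpacingStats(m, "analytic", 0, None, None, None, None)
    return SpacingStats(
        motif=m,
        sequence_id="analytic",
        n_sites=0,
        sequence_length=None,
        mean_distance_bp=1.0 / p,
        density_per_kb=1000.0 * p,
        expected_product_bp=1.0 / (2.0 * p),
    )


def genome_report(fasta_path, motifs: Sequence) -> pd.DataFrame:
    """Per-record and pooled spacing statistics for each motif in a FASTA file.

    Pooled (“genome”) rows aggregate counts over records; the pooled mean
    distance uses within-record gaps only — a gap never spans a record
    boundary, because distances across scaffolds are meaningless.
    """
    records = read_fasta(fasta_path)
    rows = []
    for motif in motifs:
        all_gaps = []
        total_sites = 0
        total_len = 0
        for rec in records:
            sites = scan_pst_sites(rec, motif)
            total_sites += sites.n_sites
            total_len += sites.sequence_length
            if sites.n_sites >= 2:
                all_gaps.append(np.diff(sites.positions))
            rows.append(spacing_stats(sites))
        pooled_gaps = np.concatenate(all_gaps) if all_gaps else np.array([])
        rows.append(
            _stats_from_gaps(_as_str(motif), "__pooled__", total_sites, total_len, pooled_gaps)
        )
    return pd.DataFrame([vars(r) for r in rows])


def sites_to_bed(site_sets: Iterable[PalindromeSiteSet]) -> pd.DataFrame:
    """BED6 table of sites (strand '.': palindromes are strand-symmetric)."""
    rows = [
        {
            "chrom": s.sequence_id,
            "chromStart": p,
            "chromEnd": p + len(s.motif),
            "name": s.motif,
            "score": 0,
            "strand": ".",
        }
        for s in site_sets
        for p in s.positions
    ]
    return pd.DataFrame(rows, columns=["chrom", "chromStart", "chromEnd", "name", "score", "strand"])
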