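"""Primer sequence metrics: GC%, nearest-neighbor Tm, linguistic complexity,
and combinatorial hairpin / primer-dimer screens.

The melting temperature uses the unified nearest-neighbor DNA duplex
parameter set (per-stack enthalpy/entropy plus initiation and terminal A:T
terms), with the divalent cation folded into an effective monovalent
concentration by the standard square-root equivalence
(``Na_eq = mono + 120 * sqrt(Mg)``, all in mM) and an entropic salt
correction of ``0.368 * (N-1) * ln[Na_eq]``.  Degenerate positions
contribute the arithmetic mean of the stack parameters over their allowed
realizations — the expected behaviour of an equimolar degenerate pool.

The structure screens are deliberately combinatorial (complementarity runs
scored 3 per G:C and 2 per A:T pair), not free-energy minimization: they are
used as qualitative design filters and are exactly checkable by brute force.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from itertools import product
from typing import Iterable

import pandas as pd

from .sequences import AMBIGUITY, NucleotideSequence, SequenceError, _as_str

__all__ = [
    "IonicConditions",
    "PST_CONDITIONS",
    "SSP_CONDITIONS",
    "DuplexReport",
    "gc_percent",
    "melting_temperature",
    "linguistic_complexity",
    "hairpin_screen",
    "dimer_screen",
    "round_half_up",
    "metrics_table",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (56.25 -> 56.3), matching printed catalogs."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class IonicConditions:
    """Reaction conditions entering the Tm calculation.

    monovalent_mM: K+/NH4+ concentration; divalent_mM: Mg2+;
    primer_uM: primer concentration (primer assumed in excess of template).
    """

    monovalent_mM: float
    divalent_mM: float
    primer_uM: float

    def __post_init__(self) -> None:
        if min(self.monovalent_mM, self.divalent_mM, self.primer_uM) < 0:
            raise ValueError("concentrations must be non-negative")

    @property
    def effective_monovalent_mM(self) -> float:
        """Monovalent concentration with Mg2+ folded in by sqrt equivalence."""
        return self.monovalent_mM + 120.0 * math.sqrt(self.divalent_mM)


#: first-round PST primer conditions: 50 mM monovalent, 2 mM Mg2+, 0.5 uM primer
PST_CONDITIONS = IonicConditions(50.0, 2.0, 0.5)
#: SSP / tail-primer conditions: 50 mM monovalent, no Mg2+, 0.25 uM primer
SSP_CONDITIONS = IonicConditions(50.0, 0.0, 0.25)


def gc_percent(seq) -> float:
    """GC percentage with degenerate-base weighting.

    Each residue contributes the G+C fraction of its allowed set: 1 for
    G/C/S, 0 for A/T/W, 0.5 for N/R/Y/K/M, 2/3 for B/V, 1/3 for D/H.
    """
    s = _as_str(seq)
    if not s:
        raise SequenceError("GC% of an empty sequence is undefined")
    total = 0.0
    for ch in s:
        allowed = AMBIGUITY[ch]
        total += len(allowed & {"G", "C"}) / len(allowed)
    return 100.0 * total / len(s)


# Unified nearest-neighbor duplex parameters, keyed by plus-strand
# dinucleotide: (delta_H kcal/mol, delta_S cal/(mol*K)).
NN_STACKS: dict[str, tuple[float, float]] = {
    "AA": (-7.6, -21.3), "TT": (-7.6, -21.3),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
NN_INITIATION = (0.2, -5.7)
NN_TERMINAL_AT = (2.2, 6.9)
_R = 1.987  # cal/(mol*K)


def _mean_stack(d1: str, d2: str) -> tuple[float, float]:
    """Average stack parameters over all realizations of a degenerate step."""
    hs = ss = 0.0
    combos = [(a, b) for a in AMBIGUITY[d1] for b in AMBIGUITY[d2]]
    for a, b in combos:
        h, s = NN_STACKS[a + b]
        hs += h
        ss += s
    return hs / len(combos), ss / len(combos)


def melting_temperature(seq, cond: IonicConditions = PST_CONDITIONS) -> float:
    """Nearest-neighbor melting temperature in degrees Celsius.

    Requires length >= 8 (shorter oligos give no meaningful stack
    statistics for PCR primers).  Degenerate codes are averaged.
    """
    s = _as_str(seq)
    if len(s) < 8:
        raise SequenceError(f"sequence too short for NN Tm: {len(s)} < 8")
    dh, ds = NN_INITIATION
    for i in range(len(s) - 1):
        h, v = _mean_stack(s[i], s[i + 1])
        dh += h
        ds += v
    # terminal A:T penalties, weighted by the A/T fraction of degenerate ends
    for end in (s[0], s[-1]):
        w = len(AMBIGUITY[end] & {"A", "T"}) / len(AMBIGUITY[end])
        dh += w * NN_TERMINAL_AT[0]
        ds += w * NN_TERMINAL_AT[1]
    na_eq = cond.effective_monovalent_mM
    ds_corr = ds + 0.368 * (len(s) - 1) * math.log(na_eq / 1000.0)
    ct = cond.primer_uM * 1e-6  # primer in excess of template
    return 1000.0 * dh / (ds_corr + _R * math.log(ct)) - 273.15


def linguistic_complexity(seq, max_word: int = 2) -> float:
    """Vocabulary-usage complexity over word lengths 1..max_word, in percent.

    100 * (distinct k-mers observed) / (maximum attainable for this length),
    where the per-k maximum is min(4^k, L - k + 1).  Defined on unambiguous
    sequences only.
    """
    s = _as_str(seq)
    if any(ch not in "ACGT" for ch in s):
        raise SequenceError("linguistic complexity requires unambiguous residues")
    if len(s) < max_word:
        raise SequenceError(f"sequence shorter than max word length {max_word}")
    observed = 0
    attainable = 0
    for k in range(1, max_word + 1):
        observed += len({s[i : i + k] for i in range(len(s) - k + 1)})
        attainable += min(4 ** k, len(s) - k + 1)
    return 100.0 * observed / attainable


# ---------------------------------------------------------------------------
# hairpin / dimer screens

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def _can_pair(a: str, b: str) -> bool:
    # degenerate positions are treated as non-pairing in the screens
    return (a, b) in _PAIRS


def _pair_weight(a: str) -> int:
    return 3 if a in "GC" else 2


@dataclass(frozen=True)
class DuplexReport:
    """One complementarity run found by a structure screen.

    Spans are half-open index ranges on each partner; pairing is antiparallel
    (first base of span_a pairs last base of span_b).
    """

    partner_kind: str  # self-hairpin | self-dimer | cross-dimer
    paired_span_a: tuple[int, int]
    paired_span_b: tuple[int, int]
    involves_3prime_terminus: bool
    stability_score: int

    @property
    def stem_length(self) -> int:
        return self.paired_span_a[1] - self.paired_span_a[0]


def hairpin_screen(primer, min_stem: int = 4, min_loop: int = 3) -> list[DuplexReport]:
    """Maximal intramolecular stems with stem >= min_stem and loop >= min_loop.

    A stem pairs s[i..i+k) antiparallel with s[j..j+k) (j > i); the loop is
    the unpaired stretch between the inner ends of the two arms.  For every
    antidiagonal the longest admissible stem is reported; stems wholly
    contained in a reported one are suppressed.
    """
    s = _as_str(primer)
    n = len(s)
    reports: list[DuplexReport] = []
    for c in range(2 * n - 1):  # c = i + j, i < j
        i = max(0, c - n + 1)
        runs: list[tuple[int, int]] = []  # (start_i, length) of pairing runs
        start = None
        while 2 * i < c:
            j = c - i
            if j < n and _can_pair(s[i], s[j]):
                if start is None:
                    start = i
            else:
                if start is not None:
                    runs.append((start, i - start))
                    start = None
            i += 1
        if start is not None:
            runs.append((start, i - start))
        for i0, run_len in runs:
            # deepest inner arm index still leaving a loop of min_loop
            inner_limit = (c - 1 - min_loop) // 2
            k = min(run_len, inner_limit - i0 + 1)
            if k < min_stem:
                continue
            span_a = (i0, i0 + k)
            span_b = (c - i0 - k + 1, c - i0 + 1)
            reports.append(
                DuplexReport(
                    "self-hairpin",
                    span_a,
                    span_b,
                    involves_3prime_terminus=span_b[1] == n,
                    stability_score=sum(_pair_weight(s[t]) for t in range(*span_a)),
                )
            )
    return reports


def dimer_screen(a, b=None, min_run: int = 4) -> list[DuplexReport]:
    """Maximal ungapped antiparallel complementary runs between two primers.

    With ``b`` omitted (or identical to ``a``) this is a self-dimer screen.
    Runs are flagged when they reach either primer's 3'-terminal base.
    """
    sa = _as_str(a)
    is_self = b is None or _as_str(b) == sa
    sb = sa if is_self else _as_str(b)
    if not sa or not sb:
        raise SequenceError("dimer screen requires non-empty sequences")
    la, lb = len(sa), len(sb)
    reports: list[DuplexReport] = []
    seen: set[tuple[int, int, int]] = set()
    for c in range(la + lb - 1):  # c = i + j: sa[i] pairs sb[j]
        i = max(0, c - lb + 1)
        i_hi = min(la - 1, c)
        start = None
        while i <= i_hi:
            j = c - i
            if _can_pair(sa[i], sb[j]):
                if start is None:
                    start = i
            else:
                if start is not None:
                    _emit_run(reports, seen, sa, sb, c, start, i - start, min_run, is_self)
                    start = None
            i += 1
        if start is not None:
            _emit_run(reports, seen, sa, sb, c, start, i - start, min_run, is_self)
    return reports


def _emit_run(reports, seen, sa, sb, c, i0, run_len, min_run, is_self) -> None:
    if run_len < min_run:
        return
    key = (c, i0, run_len)
    if key in seen:
        return
    seen.add(key)
    span_a = (i0, i0 + run_len)
    span_b = (c - i0 - run_len + 1, c - i0 + 1)
    reports.append(
        DuplexReport(
            "self-dimer" if is_self else "cross-dimer",
            span_a,
            span_b,
            involves_3prime_terminus=(span_a[1] == len(sa)) or (span_b[1] == len(sb)),
            stability_score=sum(_pair_weight(sa[t]) for t in range(*span_a)),
        )
    )


def metrics_table(entries: Iterable[tuple[str, NucleotideSequence, str | None]],
                  cond: IonicConditions = PST_CONDITIONS) -> pd.DataFrame:
    """Catalog-style metrics report.

    *entries* are (id, sequence, palindrome-or-None) triples; the GC% and Tm
    are computed on the given sequence, LC on the palindrome when present.
    """
    rows = []
    for pid, seq, palindrome in entries:
        rows.append(
            {
                "id": pid,
                "sequence": str(seq),
                "palindrome": palindrome or "",
                "Tm_C": round_half_up(melting_temperature(seq, cond), 1),
                "GC_pct": round_half_up(gc_percent(seq), 1),
                "LC_pct": int(round_half_up(linguistic_complexity(palindrome)))
                if palindrome
                else pd.NA,
            }
        )
    return pd.DataFrame(rows)
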