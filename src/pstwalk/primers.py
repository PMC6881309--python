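"""PST walking primers and sequence-specific primers (SSPs).

A PST primer is built 5'->3' as

    adapter (19 nt, invariant) + fully degenerate block (8-12 N) + palindrome (6 nt)

The degenerate block plus the 3' palindrome form the *core*: the only part
expected to base-pair with template.  The bundled catalog ships 25 PST
primers covering common 6-nt restriction sites, the universal tail primer
(identical to the adapter, used in the second PCR round), and the SSPs used
to walk the grass VRN1 gene.  Validation rules implement the published
design heuristics: palindrome GC in the 33-67% band for PST primers, and for
SSPs a 25-35 nt length, 40-60% GC, Tm >= 65 C and no 3'-anchored self-dimer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import pandas as pd

from .metrics import (
    SSP_CONDITIONS,
    IonicConditions,
    dimer_screen,
    gc_percent,
    linguistic_complexity,
    melting_temperature,
    round_half_up,
)
from .sequences import NucleotideSequence, is_palindrome

__all__ = [
    "PSTPrimer",
    "SSP",
    "ValidationVerdict",
    "build_pst_primer",
    "validate_pst_primer",
    "validate_ssp",
    "load_catalog",
    "catalog_tables",
    "verdicts_table",
]

DEGENERATE_RANGE = (8, 12)
EXPECTED_ADAPTER_LEN = 19
PALINDROME_GC_BAND = (33.3, 66.7)


@dataclass(frozen=True)
class PSTPrimer:
    id: str
    adapter: NucleotideSequence
    degenerate_len: int
    palindrome: NucleotideSequence
    enzyme_name: str = ""

    @property
    def core(self) -> NucleotideSequence:
        """Degenerate block + 3' palindrome: the template-pairing part."""
        return NucleotideSequence("N" * self.degenerate_len) + self.palindrome

    @property
    def full_sequence(self) -> NucleotideSequence:
        return NucleotideSequence(
            self.adapter.residues + "N" * self.degenerate_len + self.palindrome.residues,
            self.id,
        )


@dataclass(frozen=True)
class SSP:
    """Sequence-specific primer with orientation on its reference.

    Orientation F primers anneal to the minus strand and extend rightward on
    the plus strand; R primers the converse.
    """

    id: str
    sequence: NucleotideSequence
    orientation: str  # F | R
    target_note: str = ""
    nested_parent: Optional[str] = None

    def __post_init__(self) -> None:
        if self.orientation not in {"F", "R"}:
            raise ValueError(f"SSP orientation must be F or R, got {self.orientation!r}")


@dataclass(frozen=True)
class ValidationVerdict:
    rule_id: str
    passed: bool
    observed: object
    allowed: str
    advisory: bool = False


def build_pst_primer(adapter, palindrome, degenerate_len: int = 10,
                     id: str = "", enzyme_name: str = "") -> PSTPrimer:
    """Assemble and check a PST primer.

    The 3' block must be a true palindrome and the degenerate block length
    must lie in the 8-12 nt design range.
    """
    adapter = adapter if isinstance(adapter, NucleotideSequence) else NucleotideSequence(str(adapter))
    palindrome = (
        palindrome if isinstance(palindrome, NucleotideSequence) else NucleotideSequence(str(palindrome))
    )
    if not adapter.is_unambiguous:
        raise ValueError("adapter must be unambiguous")
    if not is_palindrome(palindrome):
        raise ValueError(f"{palindrome.residues!r} is not a palindrome")
    lo, hi = DEGENERATE_RANGE
    if not lo <= degenerate_len <= hi:
        raise ValueError(
            f"degenerate block of {degenerate_len} nt outside the {lo}-{hi} nt design range"
        )
    return PSTPrimer(id or f"pst-{palindrome.residues}", adapter, degenerate_len,
                     palindrome, enzyme_name)


def validate_pst_primer(p: PSTPrimer) -> list[ValidationVerdict]:
    """Design-rule verdicts for a PST primer (advisory, never exceptions)."""
    verdicts = []
    gc = round_half_up(gc_percent(p.palindrome), 1)
    lo, hi = PALINDROME_GC_BAND
    verdicts.append(
        ValidationVerdict("palindrome_gc", lo <= gc <= hi, gc,
                          f"[{lo}, {hi}] %", advisory=True)
    )
    lc = int(round_half_up(linguistic_complexity(p.palindrome)))
    verdicts.append(ValidationVerdict("palindrome_lc", True, lc, "reported only"))
    # the adapter 3' end must not be complementary to the core, or the
    # polymerase could extend adapter-core duplexes into artifacts
    runs = dimer_screen(p.adapter, p.core)
    clash = any(r.paired_span_a[1] == len(p.adapter) for r in runs)
    verdicts.append(
        ValidationVerdict("adapter_3prime_clear", not clash,
                          f"{sum(1 for _ in runs)} run(s)", "no adapter-3'-anchored run")
    )
    verdicts.append(
        ValidationVerdict("adapter_length", len(p.adapter) == EXPECTED_ADAPTER_LEN,
                          len(p.adapter), f"= {EXPECTED_ADAPTER_LEN} nt", advisory=True)
    )
    return verdicts


def _longest_common_substring(a: str, b: str) -> int:
    best = 0
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best


def validate_ssp(s: SSP, cond: IonicConditions = SSP_CONDITIONS,
                 parent: Optional[SSP] = None, min_dimer_run: int = 4) -> list[ValidationVerdict]:
    """Design-rule verdicts for a sequence-specific primer.

    Length 25-35 nt, weighted GC 40-60%, Tm >= 65 C under *cond*, no
    self-dimer run reaching the 3' terminus, and (when the outer primer is
    supplied) no long shared subsequence between nested and outer primer.
    The Tm rule is advisory: published working SSPs sit a few degrees below
    the stated threshold under the catalog's own printed conditions.
    """
    seq = s.sequence
    verdicts = [
        ValidationVerdict("length", 25 <= len(seq) <= 35, len(seq), "[25, 35] nt"),
        ValidationVerdict(
            "gc", 40.0 <= round_half_up(gc_percent(seq), 1) <= 60.0,
            round_half_up(gc_percent(seq), 1), "[40, 60] %",
        ),
        ValidationVerdict(
            "tm", melting_temperature(seq, cond) >= 65.0,
            round_half_up(melting_temperature(seq, cond), 1), ">= 65 C", advisory=True,
        ),
    ]
    runs = dimer_screen(seq, min_run=min_dimer_run)
    anchored = any(r.involves_3prime_terminus for r in runs)
    verdicts.append(
        ValidationVerdict("self_dimer", not anchored, f"{len(runs)} run(s)",
                          f"no 3'-anchored run >= {min_dimer_run}")
    )
    if s.nested_parent and parent is not None:
        lcs = _longest_common_substring(seq.residues, parent.sequence.residues)
        verdicts.append(
            ValidationVerdict("nested_overlap", lcs < 12, lcs,
                              "shared stretch < 12 nt with outer primer", advisory=True)
        )
    return verdicts


def _data_frame(name: str) -> pd.DataFrame:
    with resources.files("pstwalk.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def catalog_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw bundled catalogs (PST primers, SSPs) including printed metric columns."""
    return _data_frame("pst_primers.tsv"), _data_frame("ssp_primers.tsv")


def load_catalog() -> tuple[list[PSTPrimer], NucleotideSequence, list[SSP]]:
    """Bundled primer catalog: (PST primers, tail primer, SSPs).

    Every PST primer is re-assembled through :func:`build_pst_primer`, so a
    corrupt data file fails loudly.  The tail primer is the shared adapter.
    """
    pst_df, ssp_df = catalog_tables()
    primers = [
        build_pst_primer(row.adapter, row.palindrome, int(row.n_len),
                         id=row.id, enzyme_name=row.enzyme)
        for row in pst_df.itertuples()
    ]
    adapters = {p.adapter.residues for p in primers}
    if len(adapters) != 1:
        raise ValueError("catalog integrity error: adapters differ between PST primers")
    tail = NucleotideSequence(adapters.pop(), "5600")
    ssps = [
        SSP(row.id, NucleotideSequence(row.sequence, row.id), row.orientation,
            row.target_note, row.nested_parent if isinstance(row.nested_parent, str) and row.nested_parent else None)
        for row in ssp_df.itertuples()
    ]
    return primers, tail, ssps


def verdicts_table(named_verdicts: dict[str, list[ValidationVerdict]]) -> pd.DataFrame:
    """Flatten {primer id: verdict list} into a report table."""
    rows = [
        {
            "id": pid,
            "rule": v.rule_id,
            "passed": v.passed,
            "observed": v.observed,
            "allowed": v.allowed,
            "advisory": v.advisory,
        }
        for pid, vs in named_verdicts.items()
        for v in vs
    ]
    return pd.DataFrame(rows)
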