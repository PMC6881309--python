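"""Virtual two-round PST-PCR on arbitrary templates.

Round 1 pairs one sequence-specific primer (SSP) with one PST walking
primer: the SSP anneals in the known region and extends into the unknown;
the PST primer anchors at a palindromic site in the unknown region, its
fully degenerate block pairing with whichever flank of the site faces the
SSP, and extends back.  Round 2 re-amplifies with the SSP (same or nested)
plus the universal tail primer, which anneals to the adapter copied in from
the PST primer's 5' end.  Because the tail primer equals the 19-nt adapter,
round-1 and round-2 product lengths coincide when the same SSP is reused.

Products flanked by PST primers at both ends (RAPD-like side products) can
be enumerated separately; they are flagged, never scored — the published
protocol suppresses them kinetically.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import pandas as pd

from .primers import PSTPrimer, SSP
from .scan import scan_pst_sites
from .sequences import (
    AMBIGUITY,
    GenomicInterval,
    NucleotideSequence,
    _as_str,
    reverse_complement,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AnnealingSite",
    "AmpliconPrediction",
    "PCRConfig",
    "THERMAL_PROFILE",
    "find_ssp_sites",
    "find_pst_anneal",
    "predict_amplicons",
    "enumerate_side_products",
    "run_walk",
    "amplicons_table",
    "render_product",
]

#: recommended cycling conditions, carried as protocol metadata in outputs
THERMAL_PROFILE = {
    "round1_initial_denaturation": "95 C (2 min)",
    "round1_linear": "7-18 cycles: 95 C (15 sec), 65-72 C (20 sec), 72 C (1 min)",
    "round1_exponential": "12-18 cycles: 95 C (15 sec), 50-60 C (15 sec), 72 C (1 min)",
    "dilution": "5-10 times",
    "round2_initial_denaturation": "95 C (1 min)",
    "round2_exponential": "28-32 cycles: 95 C (15 sec), 68-72 C (70 sec)",
    "final_extension": "72 C (2 min)",
}


@dataclass(frozen=True)
class PCRConfig:
    """Amplification bounds and annealing stringency.

    The 3 kb ceiling is the practical limit of common thermophilic
    polymerases; 100 bp is the lower bound of useful second-round products.
    SSP annealing is exact by default, with a mandatory perfect 3' seed.
    """

    max_product_bp: int = 3000
    min_product_bp: int = 100
    ssp_max_mismatches: int = 0
    ssp_seed_len: int = 3
    report_side_products: bool = False
    second_round_ssp: str = "same"  # "same" or the id of a nested SSP

    def __post_init__(self) -> None:
        if not 0 < self.min_product_bp < self.max_product_bp:
            raise ValueError("need 0 < min_product_bp < max_product_bp")


@dataclass(frozen=True)
class AnnealingSite:
    primer_id: str
    footprint: GenomicInterval
    strand: str  # + extends toward higher coordinates, - toward lower
    mismatches: int
    three_prime_position: int


@dataclass(frozen=True)
class AmpliconPrediction:
    ssp_id: Optional[str]
    pst_primer_id: str
    template_interval: GenomicInterval
    round1_len_bp: int
    round2_len_bp: int
    orientation: str  # SSP-forward | SSP-reverse | PST-PST
    side_product: bool = False


def _iter_window_matches(template: str, primer: str):
    """Overlapping start positions where *primer* (IUPAC) matches exactly."""
    pattern = "(?=(" + "".join("[" + "".join(sorted(AMBIGUITY[c])) + "]" for c in primer) + "))"
    for m in re.finditer(pattern, template):
        yield m.start()


def find_ssp_sites(template, ssp: SSP, cfg: PCRConfig = PCRConfig()) -> list[AnnealingSite]:
    """All annealing footprints of an SSP on either strand of the template.

    Degenerate primer codes match per IUPAC semantics; template positions
    outside A/C/G/T never anneal.  The primer's 3'-terminal ``ssp_seed_len``
    bases must match exactly regardless of the mismatch allowance.
    """
    t = _as_str(template)
    p = _as_str(ssp.sequence)
    name = template.name if isinstance(template, NucleotideSequence) else ""
    sites: list[AnnealingSite] = []
    rc = reverse_complement(ssp.sequence).residues
    if cfg.ssp_max_mismatches == 0:
        plus_starts = _iter_window_matches(t, p)
        minus_starts = _iter_window_matches(t, rc)
    else:
        plus_starts = _mismatch_scan(t, p, cfg.ssp_max_mismatches, cfg.ssp_seed_len, seed_at_end=True)
        minus_starts = _mismatch_scan(t, rc, cfg.ssp_max_mismatches, cfg.ssp_seed_len, seed_at_end=False)
    for start in plus_starts:
        mm = _count_mismatches(t[start : start + len(p)], p)
        sites.append(
            AnnealingSite(ssp.id, GenomicInterval(name, start, start + len(p), "+"),
                          "+", mm, start + len(p) - 1)
        )
    for start in minus_starts:
        mm = _count_mismatches(t[start : start + len(rc)], rc)
        sites.append(
            AnnealingSite(ssp.id, GenomicInterval(name, start, start + len(rc), "-"),
                          "-", mm, start)
        )
    sites.sort(key=lambda s: (s.footprint.start, s.strand))
    return sites


def _count_mismatches(window: str, primer: str) -> int:
    return sum(1 for w, c in zip(window, primer) if w not in AMBIGUITY[c] or w not in "ACGT")


def _mismatch_scan(t: str, primer: str, max_mm: int, seed_len: int, seed_at_end: bool):
    l = len(primer)
    seed = range(l - seed_len, l) if seed_at_end else range(seed_len)
    for start in range(len(t) - l + 1):
        window = t[start : start + l]
        mm = 0
        ok = True
        for i, (w, c) in enumerate(zip(window, primer)):
            if w in AMBIGUITY[c] and w in "ACGT":
                continue
            if i in seed:
                ok = False
                break
            mm += 1
            if mm > max_mm:
                ok = False
                break
        if ok:
            yield start


def find_pst_anneal(template, pst: PSTPrimer, window: Optional[GenomicInterval] = None,
                    direction: Optional[str] = None) -> list[AnnealingSite]:
    """PST-primer annealing candidates at palindromic sites in a window.

    At each site the degenerate block can pair with either flank, giving two
    orientations: strand "+" pairs the left flank and extends rightward,
    strand "-" pairs the right flank and extends leftward.  An orientation
    is dropped when its flank runs off the template or contains an
    ambiguous base (N never pairs).  ``direction`` restricts to one strand.
    """
    t = _as_str(template)
    name = template.name if isinstance(template, NucleotideSequence) else ""
    d = pst.degenerate_len
    m = len(pst.palindrome)
    lo = window.start if window else 0
    hi = window.end if window else len(t)
    sites: list[AnnealingSite] = []
    for q in scan_pst_sites(template, pst.palindrome).positions:
        if not (lo <= q and q + m <= hi):
            continue
        # "+": degenerate block pairs the left flank, extension rightward
        if direction in (None, "+") and q - d >= 0 and all(b in "ACGT" for b in t[q - d : q]):
            sites.append(
                AnnealingSite(pst.id, GenomicInterval(name, q - d, q + m, "+"),
                              "+", 0, q + m - 1)
            )
        # "-": degenerate block pairs the right flank, extension leftward
        if direction in (None, "-") and q + m + d <= len(t) and all(
            b in "ACGT" for b in t[q + m : q + m + d]
        ):
            sites.append(
                AnnealingSite(pst.id, GenomicInterval(name, q, q + m + d, "-"),
                              "-", 0, q)
            )
    return sites


def predict_amplicons(template, ssp: SSP, pst: PSTPrimer, tail,
                      cfg: PCRConfig = PCRConfig(),
                      nested_ssp: Optional[SSP] = None) -> list[AmpliconPrediction]:
    """Predicted products of the two-round reaction for one SSP/PST pair.

    For every SSP annealing site, every correctly oriented PST site lying in
    the SSP's extension direction within the amplifiable range yields one
    product.  Round-2 length replaces the PST adapter with the equal-length
    tail primer; with a nested second-round SSP the length is recomputed
    from the nested primer's 5' coordinate inside the round-1 product.
    """
    tail_s = _as_str(tail)
    if tail_s != pst.adapter.residues:
        raise ValueError("tail primer must equal the PST adapter sequence "
                         "(the tail anneals to the copied adaptor)")
    t = _as_str(template)
    a = len(tail_s)
    preds: list[AmpliconPrediction] = []
    ssp_sites = find_ssp_sites(template, ssp, cfg)
    nested_sites = find_ssp_sites(template, nested_ssp, cfg) if nested_ssp else None
    for s in ssp_sites:
        if s.strand == "+":
            window = GenomicInterval(s.footprint.sequence_id, s.footprint.end, len(t))
            for anchor in find_pst_anneal(template, pst, window, direction="-"):
                far = anchor.footprint.end  # q + m + d
                span = GenomicInterval(s.footprint.sequence_id, s.footprint.start, far)
                round1 = (far - s.footprint.start) + a
                round2 = round1
                if nested_sites is not None:
                    inner = [n for n in nested_sites
                             if n.strand == "+" and span.contains(n.footprint)]
                    if not inner:
                        continue
                    n5 = min(n.footprint.start for n in inner)
                    round2 = (far - n5) + a
                preds.append(
                    AmpliconPrediction(ssp.id, pst.id, span, round1, round2, "SSP-forward")
                )
        else:
            window = GenomicInterval(s.footprint.sequence_id, 0, s.footprint.start)
            for anchor in find_pst_anneal(template, pst, window, direction="+"):
                far = anchor.footprint.start  # q - d
                span = GenomicInterval(s.footprint.sequence_id, far, s.footprint.end)
                round1 = (s.footprint.end - far) + a
                round2 = round1
                if nested_sites is not None:
                    inner = [n for n in nested_sites
                             if n.strand == "-" and span.contains(n.footprint)]
                    if not inner:
                        continue
                    n5 = max(n.footprint.end for n in inner)
                    round2 = (n5 - far) + a
                preds.append(
                    AmpliconPrediction(ssp.id, pst.id, span, round1, round2, "SSP-reverse")
                )
    preds = [p for p in preds if cfg.min_product_bp <= p.round2_len_bp <= cfg.max_product_bp]
    preds.sort(key=lambda p: (p.round2_len_bp, p.template_interval.start))
    return preds


def enumerate_side_products(template, pst: PSTPrimer,
                            cfg: PCRConfig = PCRConfig()) -> list[AmpliconPrediction]:
    """RAPD-like products bounded by PST primers at both ends.

    Two sites of the same motif on facing orientations (left site extending
    rightward, right site extending leftward) within the amplifiable range
    give one flagged side product.
    """
    name = template.name if isinstance(template, NucleotideSequence) else ""
    a = len(pst.adapter)
    left = find_pst_anneal(template, pst, direction="+")
    right = find_pst_anneal(template, pst, direction="-")
    m = len(pst.palindrome)
    preds = []
    for la in left:
        for ra in right:
            q1 = la.footprint.end - m  # site start of the left anchor
            q2 = ra.footprint.start
            if q2 < q1 + m:  # cores must not overlap
                continue
            span = GenomicInterval(name, la.footprint.start, ra.footprint.end)
            length = len(span) + 2 * a
            if cfg.min_product_bp <= length <= cfg.max_product_bp:
                preds.append(
                    AmpliconPrediction(None, pst.id, span, length, length,
                                       "PST-PST", side_product=True)
                )
    preds.sort(key=lambda p: (p.round2_len_bp, p.template_interval.start))
    return preds


def render_product(template, pred: AmpliconPrediction, pst: PSTPrimer, tail) -> NucleotideSequence:
    """Predicted round-2 product sequence, written 5'->3' from the SSP end.

    The degenerate block is rendered as N's; the strand finishes with the
    reverse complement of the tail primer.
    """
    t = _as_str(template)
    tail_rc = reverse_complement(tail).residues
    d = pst.degenerate_len
    iv = pred.template_interval
    if pred.side_product:
        body = _as_str(tail) + "N" * d + t[iv.start + d : iv.end - d] + "N" * d + tail_rc
    elif pred.orientation == "SSP-forward":
        body = t[iv.start : iv.end - d] + "N" * d + tail_rc
    else:
        body = reverse_complement(NucleotideSequence(t[iv.start + d : iv.end])).residues + "N" * d + tail_rc
    name = f"{pred.ssp_id or 'PST'}_{pred.pst_primer_id}_{iv.sequence_id}_{iv.start}_{iv.end}"
    return NucleotideSequence(body, name)


def run_walk(templates, ssp_ids: Sequence[str], catalog,
             cfg: PCRConfig = PCRConfig(),
             pst_ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Cartesian SSP x PST screen over all template records.

    *catalog* is the (pst_primers, tail, ssps) triple from
    :func:`pstwalk.primers.load_catalog`.  Rows are ordered by
    (ssp_id, pst_id, record, coordinate).  An empty result logs a hint that
    the SSP found no annealing site (the most common bench failure).
    """
    pst_primers, tail, ssps = catalog
    ssp_by_id = {s.id: s for s in ssps}
    pst_by_id = {p.id: p for p in pst_primers}
    for sid in ssp_ids:
        if sid not in ssp_by_id:
            raise KeyError(f"unknown SSP id {sid!r}; available: {sorted(ssp_by_id)}")
    chosen_pst = list(pst_ids) if pst_ids else sorted(pst_by_id)
    for pid in chosen_pst:
        if pid not in pst_by_id:
            raise KeyError(f"unknown PST primer id {pid!r}; available: {sorted(pst_by_id)}")
    if isinstance(templates, NucleotideSequence):
        templates = [templates]
    rows = []
    any_ssp_site = False
    for sid in sorted(ssp_ids):
        ssp = ssp_by_id[sid]
        nested = None
        if cfg.second_round_ssp != "same":
            nested = ssp_by_id.get(cfg.second_round_ssp)
            if nested is None:
                raise KeyError(f"unknown nested SSP id {cfg.second_round_ssp!r}")
        for rec in templates:
            if find_ssp_sites(rec, ssp, cfg):
                any_ssp_site = True
            for pid in chosen_pst:
                pst = pst_by_id[pid]
                for pred in predict_amplicons(rec, ssp, pst, tail, cfg, nested_ssp=nested):
                    rows.append(_pred_row(pred))
                if cfg.report_side_products:
                    for pred in enumerate_side_products(rec, pst, cfg):
                        rows.append(_pred_row(pred))
    if not any_ssp_site:
        logger.warning(
            "no SSP annealing site found on any template; check SSP design, "
            "template quality, or reduce annealing stringency"
        )
    df = pd.DataFrame(
        rows,
        columns=["ssp_id", "pst_id", "record", "start", "end", "strand",
                 "round1_len_bp", "round2_len_bp", "orientation", "side_product"],
    )
    return df.sort_values(
        ["ssp_id", "pst_id", "record", "start", "end"], na_position="first"
    ).reset_index(drop=True)


def _pred_row(pred: AmpliconPrediction) -> dict:
    iv = pred.template_interval
    strand = {"SSP-forward": "+", "SSP-reverse": "-", "PST-PST": "."}[pred.orientation]
    return {
        "ssp_id": pred.ssp_id,
        "pst_id": pred.pst_primer_id,
        "record": iv.sequence_id,
        "start": iv.start,
        "end": iv.end,
        "strand": strand,
        "round1_len_bp": pred.round1_len_bp,
        "round2_len_bp": pred.round2_len_bp,
        "orientation": pred.orientation,
        "side_product": pred.side_product,
    }


def amplicons_table(preds: Sequence[AmpliconPrediction]) -> pd.DataFrame:
    return pd.DataFrame([_pred_row(p) for p in preds])
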