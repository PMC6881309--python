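"""Shared fixtures and the independent string-level PCR oracle.

The oracle simulates primer extension literally on strings: it never shares
coordinate arithmetic with the package, so agreement between the two is a
real check of the amplicon geometry.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import pstwalk as pw

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

_RC = str.maketrans("ACGT", "TGCA")


def rc(s: str) -> str:
    return s.translate(_RC)[::-1]


@pytest.fixture(scope="session")
def catalog():
    return pw.load_catalog()


@pytest.fixture(scope="session")
def catalog_tables():
    return pw.catalog_tables()


def oracle_product_lengths(template: str, ssp_realized: str, adapter: str,
                           degenerate_len: int, palindrome: str, tail: str,
                           min_bp: int = 100, max_bp: int = 3000) -> list[int]:
    """Lengths of two-round walking products by literal strand building.

    For every exact SSP annealing site (either strand) the first-round
    extension strand is built as an actual string; the walking primer is
    annealed wherever its 3' palindrome finds a match with a full-length
    unambiguous flank for the degenerate block, and the second-round product
    is the primer plus the copied-back stretch, with the adapter swapped for
    the tail primer.  Returns the sorted multiset of product lengths.
    """
    assert len(tail) == len(adapter)
    d, m = degenerate_len, len(palindrome)
    lengths = []
    extension_strands = []
    # plus-strand SSP sites: extension copies template rightward
    start = template.find(ssp_realized)
    while start != -1:
        extension_strands.append((template[start:], len(ssp_realized)))
        start = template.find(ssp_realized, start + 1)
    # minus-strand SSP sites: extension strand is the reverse complement
    rc_ssp = rc(ssp_realized)
    start = template.find(rc_ssp)
    while start != -1:
        extension_strands.append((rc(template[: start + len(rc_ssp)]), len(rc_ssp)))
        start = template.find(rc_ssp, start + 1)
    for strand, ssp_len in extension_strands:
        k = strand.find(palindrome)
        while k != -1:
            flank = strand[k + m : k + m + d]
            if k >= ssp_len and len(flank) == d and all(b in "ACGT" for b in flank):
                # primer(tail + N*d + palindrome) + copy-back of strand[:k]
                product = tail + "N" * d + palindrome + rc(strand[:k])
                lengths.append(len(product))
            k = strand.find(palindrome, k + 1)
    return sorted(l for l in lengths if min_bp <= l <= max_bp)


@pytest.fixture(scope="session")
def walk_fixture(catalog):
    """One deterministic template with a known SSP site and PST site."""
    pst, tail, ssps = catalog
    ssp = next(s for s in ssps if s.id == "5315")
    rng = np.random.default_rng(7)
    ssp_real = pw.realize(ssp.sequence, rng)
    spec = pw.FixtureSpec(
        10_000, 0.5, 42,
        (pw.Implant("ssp5315", ssp_real, 100), pw.Implant("GGATCC", "GGATCC", 600)),
    )
    template, truth = pw.generate_genome(spec)
    return template, truth, ssp, ssp_real


def random_walk_case(seed: int, catalog):
    """A randomized template with one implanted SSP site and 1-4 PST sites.

    Returns (template string, realized SSP text, SSP object, PST primer).
    Used for oracle-equivalence sweeps.
    """
    pst_primers, tail, ssps = catalog
    rng = np.random.default_rng(seed)
    ssp = ssps[rng.integers(len(ssps))]
    ssp_real = pw.realize(ssp.sequence, rng)
    # avoid motifs that occur inside the realized SSP text itself
    candidates = [p for p in pst_primers
                  if p.palindrome.residues not in ssp_real
                  and p.palindrome.residues not in rc(ssp_real)]
    pst = candidates[rng.integers(len(candidates))]
    length = int(rng.integers(4000, 8001))
    gc = float(rng.uniform(0.35, 0.65))
    ssp_strand = "+" if rng.random() < 0.5 else "-"
    ssp_pos = int(rng.integers(50, length // 4))
    implants = [pw.Implant("ssp", ssp_real, ssp_pos, ssp_strand)]
    n_sites = int(rng.integers(1, 5))
    taken = [(ssp_pos, ssp_pos + len(ssp_real))]
    for _ in range(n_sites):
        for _attempt in range(100):
            pos = int(rng.integers(20, length - 40))
            if all(pos + 26 <= s or pos >= e + 20 for s, e in taken):
                taken.append((pos, pos + 6))
                implants.append(pw.Implant("site", pst.palindrome.residues, pos))
                break
    spec = pw.FixtureSpec(length, gc, int(rng.integers(2**31)), tuple(implants))
    template, _ = pw.generate_genome(spec)
    return template, ssp_real, ssp, pst
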