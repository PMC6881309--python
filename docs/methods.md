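# Methods note

This note records the models, conventions and numerical choices behind
`pstwalk`, and what they deliberately do not cover.

## Coordinate and sequence conventions

- All coordinates are **0-based, half-open** (`GenomicInterval(start, end)`),
  matching BED. Strand is `+`, `-`, or `.`; palindromic-motif intervals are
  strand-symmetric and carry `.`.
- Sequences are canonicalized to upper case on ingest and `U` is mapped to
  `T`. Every residue must be an IUPAC code; validation errors name the
  offending position.
- Palindromy (`is_palindrome`) is defined only on unambiguous A/C/G/T
  sequences: a sequence is palindromic iff it equals its reverse complement.
  Exactly 64 of the 4096 hexamers qualify (4³ — the first three bases are
  free, the last three determined).

## Primer model

A PST (walking) primer is `adapter + N×d + palindrome`, 5′→3′, with the
19-nt adapter `GTTGCGGCAGGTCCTCACC`, degenerate length `d ∈ [8, 12]`
(default 10) and an even-length palindrome of at least 6 nt. The *core*
(degenerate block + palindrome) is the template-pairing part. The tail
primer equals the adapter; the virtual-PCR engine enforces this
(`len(tail) == len(adapter)`), which is what makes round-1 and round-2
product lengths equal when the same SSP is reused.

Design rules implemented as verdicts (never exceptions):

- PST primers: palindrome GC within **[33.3, 66.7] %** inclusive (advisory),
  palindrome linguistic complexity (reported), no dimer run anchored at the
  adapter 3′ end against the core, adapter length 19 (advisory).
- SSPs: length 25–35 nt, GC 40–60 %, Tm ≥ 65 °C (advisory), no 3′-anchored
  self-dimer run, and — for nested primers — a longest-common-substring
  overlap with the parent below 12 nt (advisory; an exact-overlap proxy,
  since true cross-hybridization depends on thermodynamics).

The bundled catalog (25 PST primers, 12 SSPs) ships as TSV package data.
The SSP length rule flags three catalog primers (39, 36 and 23 nt) as
outside the 25–35 band; validation reports this honestly rather than
special-casing the catalog.

## Thermodynamics

- **Tm** uses the unified SantaLucia nearest-neighbor parameter set
  (duplex initiation ΔH 0.2 kcal/mol, ΔS −5.7 cal/mol·K; terminal A·T
  penalty 2.2 / 6.9), the same table Biopython exposes as `DNA_NN4`; the
  test suite cross-checks against Biopython to 0.05 °C.
- Degenerate positions average stack parameters over the allowed
  realizations (equimolar pool, "mean behavior" reading). Terminal-A/T
  penalties are weighted by the A/T fraction of the terminal code.
- Salt correction: Mg²⁺ folds into an effective monovalent concentration as
  `mono_mM + 120·√(Mg_mM)`, then the entropic correction
  `ΔS += 0.368·(N−1)·ln([Na⁺]eq)` is applied.
  `Tm = 1000·ΔH / (ΔS + R·ln CT) − 273.15` with the primer-excess
  convention for CT. Two presets are exposed: PST conditions
  (50 mM monovalent, 2 mM Mg²⁺, 0.5 µM primer) and SSP conditions
  (50 mM monovalent, no Mg²⁺, 0.25 µM primer).
- Printed catalog Tm values come from a closed-source calculator; they are
  checked only to ±3 °C for the SSPs and are not reproduced for the fully
  degenerate PST primers or the tail primer — the repository asserts only
  what it can compute with an open model.

## GC% and linguistic complexity

- GC% weights degenerate codes by the GC fraction of their allowed set
  (S = 1; N, R, Y, K, M, W handled by their sets; B/V = 2/3; D/H = 1/3).
- Linguistic complexity uses word sizes k = 1..2:
  `100 · Σ_k distinct k-mers / Σ_k min(4^k, L−k+1)`. For a 6-mer the
  denominator is 4 + 5 = 9; palindromes with a repeated dinucleotide
  vocabulary (e.g. `GCATGC`) score 8/9 → 89, maximally diverse hexamers
  score 100.
- Report columns round with **half-up** decimal rounding (one decimal for
  Tm/GC, integer for LC), not banker's rounding — 56.25 must print as 56.3.

## Structure screens

Hairpin and dimer screens are combinatorial, not free-energy minimization:
maximal complementary runs are enumerated along antidiagonals of the
pairing matrix (G·C scores 3, A·T 2; degenerate bases never pair). A
hairpin requires stem ≥ 4 with loop ≥ 3 between the paired spans. Reports
carry both paired spans, a 3′-terminus flag and the additive stability
score. Truth in the tests is established by brute-force enumeration of all
admissible span pairs.

## Site scanning and spacing statistics

Occurrences are counted on the plus strand only — a palindrome reads the
same on both strands, so this is complete (the scanner rejects
non-palindromic motifs). Overlapping occurrences count. Spacing statistics:
mean inter-site distance, density per kb, and **expected product length =
half the mean distance** (the SSP lands uniformly between two sites, and
amplification runs to the nearest usable site). The analytic i.i.d. model
gives mean distance `1/p` with `p = Π per-base probability` at the given GC
content — 4096 bp for any 6-mer at GC 0.5, 65536 bp for 8-mers. Pooled
multi-record statistics never bridge record boundaries.

## Virtual PCR

- SSP annealing: degenerate-aware exact match by default; an optional
  mismatch budget never applies to the 3-nt 3′ seed, which must match
  perfectly (extension starts there).
- PST-primer annealing: the palindrome must match exactly and the
  degenerate block's footprint must lie in-bounds over unambiguous bases.
- Product length (forward SSP, site at `q`, palindrome length `m`,
  degenerate length `d`, adapter length `a`, SSP start `s`):
  `(q + m + d − s) + a`; mirrored for reverse SSPs. Products are filtered
  to the polymerase window (defaults 100–3000 bp; the upper bound reflects
  the practical limit of most thermophilic polymerases) and the filter is
  monotone in the window. Side products (PST primer at both ends) are
  enumerated separately from facing site pairs.
- The engine is validated against an **independent string-level extension
  simulator** that builds first-round extension strands literally and never
  shares coordinate arithmetic with the package; 200 randomized fixtures
  must agree exactly.
- Thermal cycling profiles are stored as protocol metadata only (emitted as
  comments in the output); cycle counts and temperatures do not affect
  predictions.

## Synthetic fixtures

`generate_genome` draws an i.i.d. background at the requested GC content
from a seeded `numpy` generator, writes implants at fixed coordinates, then
destroys every off-implant occurrence of each implant sequence (and its
reverse complement, and any extra `exclude_motifs`) by point resampling.
The ground-truth table is therefore **exhaustive**: a scanner must report
the implants and nothing else, allowing exact assertions instead of
tolerances. `generate_population` adds one random indel per variant between
the first two implants, so product-length differences across variants equal
the implanted indel sizes exactly. The generator emulates sequence
composition and motif placement only — no repeats, chromatin, methylation
or amplification biases.

## Limitations

- Tm is an open NN model; it does not byte-match any proprietary
  calculator's output (±3 °C advisory only, and only for fully or nearly
  defined primers).
- Structure screens rank by complementarity-run score, not ΔG; no partition
  function, no multi-loop structures.
- The virtual PCR is geometric: it does not model polymerase processivity
  distributions, primer competition, or linear-phase kinetics beyond the
  anchored/side-product distinction.
- No real genome is bundled; the scanner accepts arbitrary FASTA but all
  shipped fixtures are synthetic.
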