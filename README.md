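# pstwalk

Design, screening and in-silico simulation tools for **PST-PCR**
(palindromic sequence-targeted PCR), a genome-walking technique for reading
unknown DNA adjacent to a known sequence.

## The problem

Ordinary PCR needs two primers, one on each side of the fragment to amplify.
When only one side of a region is known — a promoter upstream of a sequenced
exon, the borders of an insertion — a second anchor must be invented. PST-PCR
anchors the unknown side on **restriction-enzyme recognition sites**: short
palindromes (e.g. `GGATCC`, BamHI) that occur every few kilobases in any
genome simply by chance.

The walking primer ("PST primer") has three parts, 5′→3′:

```
GTTGCGGCAGGTCCTCACC  NNNNNNNNNN  GGATCC
└─ 19-nt adapter ──┘ └─ 10 N ──┘ └palindrome┘
```

Only the *core* (degenerate block + palindrome) base-pairs with template; the
fully degenerate N-block lets the primer land on any palindrome occurrence
regardless of flanking sequence. Two rounds of PCR are run:

1. **Round 1** — a sequence-specific primer (SSP) in the known region plus
   the PST primer. Early cycles are linear (only the SSP primes at high
   annealing temperature); later cycles let the PST primer anneal.
2. **Round 2** — on a dilution of round 1, the same (or a nested) SSP plus a
   **tail primer** identical to the 19-nt adapter, giving clean exponential
   amplification. Because the tail primer and the adapter have the same
   length, the round-2 product has the same length as the round-1 product
   when the same SSP is reused.

`pstwalk` implements the computational side of this workflow:

| Module | What it does |
|---|---|
| `pstwalk.sequences` | IUPAC sequence model, reverse complement, palindrome test, degenerate matching, FASTA I/O |
| `pstwalk.metrics` | GC% with degenerate weighting, nearest-neighbor Tm with salt correction, linguistic complexity, hairpin/self-dimer/cross-dimer screens |
| `pstwalk.primers` | PST primer and SSP construction, design-rule validation, bundled 25-primer / 12-SSP catalog |
| `pstwalk.scan` | palindrome-site scanner, inter-site spacing statistics, analytic i.i.d. spacing model, BED output |
| `pstwalk.pcr` | virtual two-round PST-PCR: SSP annealing (mismatch budget + 3′ seed), PST-primer annealing, amplicon length/coordinate prediction, side products, product rendering |
| `pstwalk.simulate` | seeded synthetic templates with implanted motifs and exhaustive ground truth, population variants with known indels |

## Worked example

Generate a 3 kb synthetic template carrying a known SSP annealing site at
position 100 and a BamHI site at position 600, then predict the walking
product. All commands are deterministic given the seed.

```console
$ pstwalk fixture --length 3000 --gc 0.5 --seed 21 \
    --implant ssp:CTGAAGCGGATCGAGAACAAGATCAACC:100 \
    --implant site:GGATCC:600 \
    --out demo.fa --truth truth.tsv
$ cat truth.tsv
feature	record	start	end	strand
ssp	fixture_seed21	100	128	+
site	fixture_seed21	600	606	+
```

Catalog SSP `5315` (`CTSAAGCGGATCGAGAACAAGATCAACC`; the `S` matches the `G`
in the implant) and PST primer `5605` (3′ palindrome `GGATCC`):

```console
$ pstwalk virtual-pcr --template demo.fa --ssp 5315 --pst 5605
# round1_initial_denaturation: 95 C (2 min)
# round1_linear: 7-18 cycles: 95 C (15 sec), 65-72 C (20 sec), 72 C (1 min)
# round1_exponential: 12-18 cycles: 95 C (15 sec), 50-60 C (15 sec), 72 C (1 min)
# dilution: 5-10 times
# round2_initial_denaturation: 95 C (1 min)
# round2_exponential: 28-32 cycles: 95 C (15 sec), 68-72 C (70 sec)
# final_extension: 72 C (2 min)
ssp_id	pst_id	record	start	end	strand	round1_len_bp	round2_len_bp	orientation	side_product
5315	5605	fixture_seed21	100	616	+	535	535	SSP-forward	False
```

The 535 bp product checks out by hand: 500 bp from the SSP 5′ end to the
palindrome, plus the 6-nt palindrome, the 10-nt degenerate block and the
19-nt tail — (600 − 100) + 6 + 10 + 19 = 535.

Validate a primer design against the catalog's rules:

```console
$ pstwalk design --pst GAATTC:10
id	rule	passed	observed	allowed	advisory
pst-GAATTC	palindrome_gc	True	33.3	[33.3, 66.7] %	True
pst-GAATTC	palindrome_lc	True	100	reported only	False
pst-GAATTC	adapter_3prime_clear	True	0 run(s)	no adapter-3'-anchored run	False
pst-GAATTC	adapter_length	True	19	= 19 nt	True
```

Scan any FASTA for palindrome sites and spacing statistics
(`pstwalk scan --fasta genome.fa --motifs GGATCC,GAATTC --bed sites.bed`);
with `--motifs catalog` all 25 catalog palindromes are scanned. On an i.i.d.
genome at GC 0.5 a 6-nt palindrome occurs on average every 4<sup>6</sup> =
4096 bp, and the expected walking-product length is half the mean inter-site
distance — the scanner reports both.

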