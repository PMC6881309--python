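"""Virtual two-round PCR: annealing models, amplicon geometry, side products."""

import numpy as np
import pytest

import pstwalk as pw
from pstwalk.pcr import (
    PCRConfig,
    enumerate_side_products,
    find_pst_anneal,
    find_ssp_sites,
    predict_amplicons,
    render_product,
    run_walk,
)
from conftest import oracle_product_lengths, random_walk_case, rc


@pytest.fixture(scope="module")
def bamhi(catalog):
    pst, _, _ = catalog
    return next(p for p in pst if p.id == "5605")  # GGATCC


@pytest.fixture(scope="module")
def tail(catalog):
    return catalog[1]


def flat_template(length: int, fill: str = "ACTG") -> list[str]:
    # repeating non-palindromic background free of catalog motifs
    return list((fill * (length // len(fill) + 1))[:length])


class TestFindSSPSites:
    def test_exact_embedded_realization_found_on_plus_strand(self, catalog):
        _, _, ssps = catalog
        ssp = next(s for s in ssps if s.id == "5315")
        real = "CTGAAGCGGATCGAGAACAAGATCAACC"  # S realized to G
        template = pw.NucleotideSequence("T" * 40 + real + "T" * 40)
        sites = find_ssp_sites(template, ssp)
        assert [(s.footprint.start, s.strand, s.mismatches) for s in sites] == [(40, "+", 0)]
        assert sites[0].three_prime_position == 40 + 28 - 1

    def test_minus_strand_site_found(self, catalog):
        _, _, ssps = catalog
        ssp = next(s for s in ssps if s.id == "5315")
        real = "CTGAAGCGGATCGAGAACAAGATCAACC"
        template = pw.NucleotideSequence("T" * 40 + rc(real) + "T" * 40)
        sites = find_ssp_sites(template, ssp)
        assert [(s.footprint.start, s.strand) for s in sites] == [(40, "-")]
        assert sites[0].three_prime_position == 40

    def test_3prime_seed_must_be_exact_even_with_mismatch_budget(self, catalog):
        _, _, ssps = catalog
        ssp = next(s for s in ssps if s.id == "5315")
        real = list("CTGAAGCGGATCGAGAACAAGATCAACC")
        real[-1] = "G"  # break the 3'-terminal base
        template = pw.NucleotideSequence("T" * 40 + "".join(real) + "T" * 40)
        cfg = PCRConfig(ssp_max_mismatches=1)
        assert find_ssp_sites(template, ssp, cfg) == []

    def test_internal_mismatch_allowed_when_budgeted(self, catalog):
        _, _, ssps = catalog
        ssp = next(s for s in ssps if s.id == "5315")
        real = list("CTGAAGCGGATCGAGAACAAGATCAACC")
        real[10] = "A" if real[10] != "A" else "G"
        template = pw.NucleotideSequence("T" * 40 + "".join(real) + "T" * 40)
        assert find_ssp_sites(template, ssp) == []  # exact mode
        sites = find_ssp_sites(template, ssp, PCRConfig(ssp_max_mismatches=1))
        assert [(s.footprint.start, s.mismatches) for s in sites] == [(40, 1)]

    def test_planted_sites_recovered_exactly(self, walk_fixture):
        template, truth, ssp, ssp_real = walk_fixture
        sites = find_ssp_sites(template, ssp)
        expected_start = int(truth[truth.feature == "ssp5315"].iloc[0].start)
        assert [(s.footprint.start, s.strand) for s in sites] == [(expected_start, "+")]


class TestFindPSTAnneal:
    def test_right_flank_pairing_gives_minus_orientation(self, bamhi):
        chars = flat_template(100)
        chars[50:56] = "GGATCC"
        template = pw.NucleotideSequence("".join(chars))
        minus = find_pst_anneal(template, bamhi, direction="-")
        assert [(a.footprint.start, a.footprint.end, a.strand) for a in minus] == [(50, 66, "-")]
        assert minus[0].three_prime_position == 50
        plus = find_pst_anneal(template, bamhi, direction="+")
        assert [(a.footprint.start, a.footprint.end) for a in plus] == [(40, 56)]

    def test_truncated_flank_orientation_absent(self, bamhi):
        chars = flat_template(60)
        chars[49:55] = "GGATCC"  # only 5 bp right flank remains
        template = pw.NucleotideSequence("".join(chars))
        assert find_pst_anneal(template, bamhi, direction="-") == []
        assert len(find_pst_anneal(template, bamhi, direction="+")) == 1

    def test_ambiguous_flank_never_pairs(self, bamhi):
        chars = flat_template(100)
        chars[50:56] = "GGATCC"
        chars[60] = "N"  # inside the right flank
        template = pw.NucleotideSequence("".join(chars))
        assert find_pst_anneal(template, bamhi, direction="-") == []


class TestPredictAmplicons:
    def test_worked_length_example(self, walk_fixture, bamhi, tail):
        # SSP 5' at 100 extending right, GGATCC at 600:
        # (600 - 100) + 6 + 10 + 19 = 535 bp
        template, _, ssp, _ = walk_fixture
        preds = predict_amplicons(template, ssp, bamhi, tail)
        assert [p.round2_len_bp for p in preds] == [535]
        assert preds[0].round1_len_bp == 535
        assert (preds[0].template_interval.start, preds[0].template_interval.end) == (100, 616)

    def test_product_beyond_polymerase_limit_dropped(self, catalog, bamhi, tail):
        _, _, ssps = catalog
        ssp = next(s for s in ssps if s.id == "5315")
        rng = np.random.default_rng(5)
        real = pw.realize(ssp.sequence, rng)
        spec = pw.FixtureSpec(
            8000, 0.5, 9,
            (pw.Implant("ssp", real, 100), pw.Implant("site", "GGATCC", 3700)),
        )
        template, _ = pw.generate_genome(spec)
        assert predict_amplicons(template, ssp, bamhi, tail) == []
        wide = PCRConfig(max_product_bp=8000)
        assert len(predict_amplicons(template, ssp, bamhi, tail, wide)) == 1

    def test_site_behind_ssp_gives_no_product(self, catalog, bamhi, tail):
        _, _, ssps = catalog
        ssp = next(s for s in ssps if s.id == "5315")
        rng = np.random.default_rng(6)
        real = pw.realize(ssp.sequence, rng)
        spec = pw.FixtureSpec(
            5000, 0.5, 10,
            (pw.Implant("site", "GGATCC", 300), pw.Implant("ssp", real, 1000)),
        )
        template, _ = pw.generate_genome(spec)
        # forward SSP looks rightward only; the site is upstream
        assert predict_amplicons(template, ssp, bamhi, tail) == []

    def test_wrong_tail_rejected(self, walk_fixture, bamhi):
        template, _, ssp, _ = walk_fixture
        with pytest.raises(ValueError, match="adaptor"):
            predict_amplicons(template, ssp, bamhi, pw.NucleotideSequence("A" * 19))

    def test_nested_second_round_shortens_product(self, catalog, bamhi, tail):
        chars = flat_template(2000)
        outer = pw.SSP("outer", pw.NucleotideSequence("GATTACAGATTACAGATTACAGATTA"), "F")
        nested = pw.SSP("nested", pw.NucleotideSequence("CCTTGGAACCTTGGAACCTTGGAACC"), "F")
        chars[100:126] = outer.sequence.residues
        chars[200:226] = nested.sequence.residues
        chars[600:606] = "GGATCC"
        template = pw.NucleotideSequence("".join(chars))
        preds = predict_amplicons(template, outer, bamhi, tail, nested_ssp=nested)
        assert [(p.round1_len_bp, p.round2_len_bp) for p in preds] == [(535, 435)]

    def test_strand_symmetry_of_product_lengths(self, catalog):
        # reverse-complementing the template preserves the product multiset
        pst_primers, tail, _ = catalog
        for seed in range(5):
            template, ssp_real, ssp, pst = random_walk_case(seed, catalog)
            fwd = sorted(
                p.round2_len_bp for p in predict_amplicons(template, ssp, pst, tail)
            )
            rev = sorted(
                p.round2_len_bp
                for p in predict_amplicons(pw.reverse_complement(template), ssp, pst, tail)
            )
            assert fwd == rev

    def test_monotone_filtering(self, catalog):
        pst_primers, tail, _ = catalog
        template, ssp_real, ssp, pst = random_walk_case(123, catalog)
        unfiltered = predict_amplicons(
            template, ssp, pst, tail, PCRConfig(min_product_bp=1, max_product_bp=len(template.residues) + 100)
        )
        lengths = [p.round2_len_bp for p in unfiltered]
        for lo, hi in [(1, 3000), (100, 3000), (100, 1000), (400, 600)]:
            sub = predict_amplicons(template, ssp, pst, tail, PCRConfig(min_product_bp=lo, max_product_bp=hi))
            assert [p.round2_len_bp for p in sub] == [l for l in lengths if lo <= l <= hi]

    def test_amplicon_interval_contains_both_footprints(self, walk_fixture, bamhi, tail):
        template, truth, ssp, _ = walk_fixture
        (pred,) = predict_amplicons(template, ssp, bamhi, tail)
        iv = pred.template_interval
        ssp_row = truth[truth.feature == "ssp5315"].iloc[0]
        site_row = truth[truth.feature == "GGATCC"].iloc[0]
        assert iv.start == ssp_row.start  # SSP 5' end
        assert iv.end == site_row.end + bamhi.degenerate_len  # PST core far edge


class TestOracleEquivalence:
    def test_lengths_match_string_extension_simulator(self, catalog):
        # randomized fixtures: every predicted length must equal the product
        # built literally by the string-level extension oracle
        _, tail, _ = catalog
        for seed in range(40):
            template, ssp_real, ssp, pst = random_walk_case(seed, catalog)
            preds = predict_amplicons(template, ssp, pst, tail)
            expected = oracle_product_lengths(
                template.residues, ssp_real, pst.adapter.residues,
                pst.degenerate_len, pst.palindrome.residues, tail.residues,
            )
            assert sorted(p.round2_len_bp for p in preds) == expected, f"seed {seed}"


class TestSideProducts:
    def test_two_facing_sites(self, bamhi):
        chars = flat_template(3000)
        chars[1000:1006] = "GGATCC"
        chars[1500:1506] = "GGATCC"
        template = pw.NucleotideSequence("".join(chars))
        preds = enumerate_side_products(template, bamhi)
        # literal construction: core-to-core span plus two 19-nt tails
        expected_len = (1506 - 1000) + 2 * bamhi.degenerate_len + 2 * 19
        assert [p.round2_len_bp for p in preds] == [expected_len]
        assert preds[0].side_product
        rendered = render_product(template, preds[0], bamhi, pw.NucleotideSequence(bamhi.adapter.residues))
        assert len(rendered) == expected_len

    def test_single_site_gives_nothing(self, bamhi):
        chars = flat_template(2000)
        chars[900:906] = "GGATCC"
        assert enumerate_side_products(pw.NucleotideSequence("".join(chars)), bamhi) == []

    def test_distant_sites_filtered(self, bamhi):
        chars = flat_template(9000)
        chars[1000:1006] = "GGATCC"
        chars[6000:6006] = "GGATCC"
        assert enumerate_side_products(pw.NucleotideSequence("".join(chars)), bamhi) == []


class TestRunWalk:
    def test_cartesian_screen_finds_exactly_implanted_combinations(self, catalog):
        pst_primers, tail, ssps = catalog
        ssp = next(s for s in ssps if s.id == "5315")
        rng = np.random.default_rng(17)
        real = pw.realize(ssp.sequence, rng)
        implants = [pw.Implant("ssp", real, 100)]
        for motif, pos in [("GGATCC", 700), ("GAATTC", 1400), ("AAGCTT", 2100)]:
            implants.append(pw.Implant(motif, motif, pos))
        panel = tuple(p.palindrome.residues for p in pst_primers)
        spec = pw.FixtureSpec(12_000, 0.5, 21, tuple(implants), exclude_motifs=panel)
        template, _ = pw.generate_genome(spec)
        table = run_walk([template], ["5315"], catalog)
        nonempty = table.groupby("pst_id").size()
        assert set(nonempty.index) == {"5605", "5608", "5610"}
        assert (nonempty == 1).all()

    def test_unknown_ids_rejected(self, catalog, walk_fixture):
        template = walk_fixture[0]
        with pytest.raises(KeyError, match="unknown SSP"):
            run_walk([template], ["9999"], catalog)
        with pytest.raises(KeyError, match="unknown PST"):
            run_walk([template], ["5315"], catalog, pst_ids=["0000"])

    def test_no_ssp_site_yields_empty_table_and_warning(self, catalog, caplog):
        template = pw.NucleotideSequence("ACGT" * 500)
        with caplog.at_level("WARNING"):
            table = run_walk([template], ["5315"], catalog)
        assert table.empty
        assert any("no SSP annealing site" in r.message for r in caplog.records)

    def test_tandem_sites_yield_multiple_products_shortest_first(self, catalog):
        pst_primers, tail, ssps = catalog
        ssp = next(s for s in ssps if s.id == "5315")
        rng = np.random.default_rng(23)
        real = pw.realize(ssp.sequence, rng)
        spec = pw.FixtureSpec(
            9000, 0.5, 33,
            (pw.Implant("ssp", real, 50),
             pw.Implant("s1", "GGATCC", 800),
             pw.Implant("s2", "GGATCC", 1600)),
        )
        template, _ = pw.generate_genome(spec)
        table = run_walk([template], ["5315"], catalog, pst_ids=["5605"])
        lens = table.round2_len_bp.tolist()
        assert len(lens) == 2 and lens == sorted(lens)

    def test_rendered_product_length_matches_prediction(self, walk_fixture, bamhi, tail):
        template, _, ssp, _ = walk_fixture
        (pred,) = predict_amplicons(template, ssp, bamhi, tail)
        rendered = render_product(template, pred, bamhi, tail)
        assert len(rendered) == pred.round2_len_bp
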