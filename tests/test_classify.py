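"""Nine-way categorisation, SNP/conservation flags, seed and context."""

import dataclasses

import pytest

from mirledit.align import Mature
from mirledit.classify import (
    CATEGORIES,
    CrossSpeciesSite,
    SiteAnnotation,
    VariantRecord,
    classify_site,
    context_preference,
    flag_conserved,
    in_seed,
    match_snp,
)
from mirledit.errors import ClassificationError


class TestClassifySite:
    def test_every_fixture_site_gets_its_expected_category(self, category_fixture):
        fx = category_fixture
        for site in fx.sites:
            is_snp = match_snp(site, fx.variants, fx.genomic_location)
            ann = classify_site(site, fx.hairpin, is_snp=is_snp)
            assert ann.category == fx.expected[site.key], site.key

    def test_category_vocabulary_is_exactly_nine(self, category_fixture):
        fx = category_fixture
        seen = {
            classify_site(
                s, fx.hairpin, is_snp=match_snp(s, fx.variants, fx.genomic_location)
            ).category
            for s in fx.sites
        }
        assert seen == set(CATEGORIES)
        assert len(CATEGORIES) == 9

    def test_central_a_to_g_names_a_to_i(self, category_fixture):
        hairpin = category_fixture.hairpin
        ann = classify_site("ex-mir-1_15_A_g", hairpin)
        assert ann.category == "A-to-I"
        assert ann.in_seed  # mature starts at 10 -> relative position 6

    def test_position_past_tail_window_is_an_error(self, category_fixture):
        hairpin = category_fixture.hairpin
        with pytest.raises(ClassificationError):
            classify_site("ex-mir-1_45_A_g", hairpin)

    def test_snp_flag_overrides_nucleotide_category(self, category_fixture):
        hairpin = category_fixture.hairpin
        ann = classify_site("ex-mir-1_15_A_g", hairpin, is_snp=True)
        assert ann.category == "SNP"


class TestMatchSnp:
    def test_partial_level_is_not_a_snp(self, category_fixture):
        fx = category_fixture
        snp_site = next(s for s in fx.sites if fx.expected[s.key] == "SNP")
        partial = dataclasses.replace(snp_site, max_level=0.8)
        assert not match_snp(partial, fx.variants, fx.genomic_location)

    def test_full_level_with_matching_variant_is_a_snp(self, category_fixture):
        fx = category_fixture
        snp_site = next(s for s in fx.sites if fx.expected[s.key] == "SNP")
        assert match_snp(snp_site, fx.variants, fx.genomic_location)

    def test_full_level_without_positional_match_is_not_a_snp(self, category_fixture):
        fx = category_fixture
        snp_site = next(s for s in fx.sites if fx.expected[s.key] == "SNP")
        elsewhere = [VariantRecord("chr1", 999_999, "A", "G")]
        assert not match_snp(snp_site, elsewhere, fx.genomic_location)

    def test_raising_level_to_one_never_flips_true_to_false(self, category_fixture):
        fx = category_fixture
        for site in fx.sites:
            before = match_snp(site, fx.variants, fx.genomic_location)
            boosted = dataclasses.replace(site, max_level=1.0)
            after = match_snp(boosted, fx.variants, fx.genomic_location)
            assert after or not before

    def test_minus_strand_complements_alleles(self, category_fixture):
        fx = category_fixture
        snp_site = next(s for s in fx.sites if fx.expected[s.key] == "SNP")
        # on the minus strand position 24 maps to origin - 23 and A>g reads T>C
        variants = [VariantRecord("chr1", 1000 - 23, "T", "C")]
        assert match_snp(snp_site, variants, ("chr1", 1000, "-"))
        assert not match_snp(snp_site, fx.variants, ("chr1", 1000, "-"))


class TestFlagConserved:
    mature = Mature("m-5p", "5p", 10, 31)

    def _annotation(self, category="A-to-I", position=13):
        return SiteAnnotation(key=f"hp_{position}_A_g", category=category)

    def test_same_type_same_mature_position_is_conserved(self):
        ann = self._annotation()  # hairpin 13 -> mature position 4
        cross = [CrossSpeciesSite("macaque", "mml-miR", 4, "A-to-I")]
        assert flag_conserved(ann, self.mature, cross)

    def test_type_mismatch_is_not_conserved(self):
        ann = self._annotation()
        cross = [CrossSpeciesSite("mouse", "mmu-miR", 4, "C-to-U")]
        assert not flag_conserved(ann, self.mature, cross)

    def test_empty_cross_species_list_is_not_conserved(self):
        assert not flag_conserved(self._annotation(), self.mature, [])

    def test_site_outside_mature_is_not_conserved(self):
        ann = SiteAnnotation(key="hp_5_A_g", category="A-to-I")
        cross = [CrossSpeciesSite("macaque", "mml-miR", 4, "A-to-I")]
        assert not flag_conserved(ann, self.mature, cross)


class TestInSeed:
    mature = Mature("m-5p", "5p", 7, 28)

    @pytest.mark.parametrize(
        "hairpin_pos,expected",
        [(8, True), (7, False), (9, True), (14, True), (15, False)],
    )
    def test_seed_is_mature_positions_two_through_eight(self, hairpin_pos, expected):
        assert in_seed(hairpin_pos, self.mature) is expected


class TestContextPreference:
    def test_planted_uag_context_gives_pure_u_and_g_columns(self):
        # hairpins built so every A-to-I site sits in a U_G context
        anns = [
            SiteAnnotation(key=f"hp{i}_9_A_g", category="A-to-I",
                           context5="U", context3="G")
            for i in range(6)
        ]
        counts, freq, excluded = context_preference(anns)
        assert excluded == 0
        assert freq.loc["U", "5'"] == 1.0
        assert freq.loc["G", "3'"] == 1.0
        assert counts["5'"].sum() == 6

    def test_single_site_with_c_c_context(self):
        ann = SiteAnnotation(key="hp_9_C_u", category="C-to-U",
                             context5="C", context3="C")
        counts, freq, _ = context_preference([ann])
        assert freq.loc["C", "5'"] == 1.0 and freq.loc["C", "3'"] == 1.0

    def test_empty_input_yields_empty_counts_without_division_error(self):
        counts, freq, excluded = context_preference([])
        assert counts.values.sum() == 0
        assert excluded == 0

    def test_site_with_missing_neighbour_is_excluded_and_counted(self):
        ok = SiteAnnotation(key="hp_9_A_g", category="A-to-I",
                            context5="U", context3="G")
        bad = SiteAnnotation(key="hp_1_A_g", category="A-to-I",
                             context5=None, context3="G")
        counts, _, excluded = context_preference([ok, bad])
        assert excluded == 1
        assert counts["5'"].sum() == 1
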