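"""Feature-based kernel: worked-example feature strings, distance bins,
lexicon matching, DrugBank cosine flags and vector assembly properties."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddikernels import feature_kernel as fk
from ddikernels.fixtures import golden_instance
from ddikernels.types import CandidateInstance, EntityMention


def make_instance(sentence, d1, d2, e1_surface="Alphadrug",
                  e2_surface="Betadrug"):
    tokens = sentence.split()
    return CandidateInstance(
        pair_id="t.p0", tokens=tokens, d1=d1, d2=d2, end=len(tokens) - 1,
        label="unknown",
        e1=EntityMention("e1", (d1, d1), e1_surface),
        e2=EntityMention("e2", (d2, d2), e2_surface))


class TestAreas:
    def test_worked_example_areas(self, golden):
        areas = fk.split_areas(golden)
        assert fk.AreaSpans.tokens(golden, areas.left) == [
            "Plasma", "concentrations", "of"]
        assert fk.AreaSpans.tokens(golden, areas.inner) == [
            "are", "decreased", "when", "administered", "with"]
        assert fk.AreaSpans.tokens(golden, areas.right) == [
            "containing", "drug0", "or", "drug0."]

    def test_drug_at_start_gives_empty_left(self):
        inst = make_instance("drug1 inhibits drug2", 0, 2)
        areas = fk.split_areas(inst)
        assert fk.AreaSpans.tokens(inst, areas.left) == []

    def test_adjacent_drugs_give_empty_inner(self):
        inst = make_instance("take drug1 drug2 today", 1, 2)
        areas = fk.split_areas(inst)
        assert fk.AreaSpans.tokens(inst, areas.inner) == []

    def test_every_non_drug_token_in_exactly_one_area(self, golden):
        areas = fk.split_areas(golden)
        covered = []
        for span in (areas.left, areas.inner, areas.right):
            a, b = span
            covered.extend(range(a, b + 1))
        expected = [i for i in range(len(golden.tokens))
                    if i not in (golden.d1, golden.d2)]
        assert sorted(covered) == expected


class TestDistance:
    @pytest.mark.parametrize("count,label", [
        (0, "0"), (5, "5"), (6, "6~7"), (7, "6~7"), (8, "8~10"),
        (15, "11~15"), (40, "31~40"), (41, "40~"), (45, "40~"), (200, "40~"),
    ])
    def test_bin_labels(self, count, label):
        assert fk.discretize_distance(count) == label

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fk.discretize_distance(-1)

    @given(st.integers(min_value=0, max_value=200))
    @settings(max_examples=201, deadline=None)
    def test_bins_partition_nonnegative_integers(self, count):
        matches = [lab for lab, lo, hi in fk.DISTANCE_BINS
                   if count >= lo and (hi is None or count <= hi)]
        assert len(matches) == 1
        assert fk.discretize_distance(count) == matches[0]


class TestAbon:
    def test_worked_example_unigrams_and_trigram(self, golden):
        feats = fk.abon_features(golden)
        for name in ("left_area=Plasma", "left_area=concentrations",
                     "left_area=of", "left_area=Plasma concentrations of",
                     "inner_area=are", "inner_area=when administered with",
                     "right_area=drug0 or drug0."):
            assert feats[name] == 1.0

    def test_empty_inner_area_yields_no_inner_features(self):
        inst = make_instance("take drug1 drug2 today", 1, 2)
        feats = fk.abon_features(inst)
        assert not any(n.startswith("inner_area=") for n in feats)


class TestSan:
    def test_worked_example_window_grams(self, golden):
        feats = fk.san_features(golden)
        for name in ("D1_left=Plasma concentrations of", "D1_right=are",
                     "D1_right=decreased", "D2_left=decreased when administered",
                     "D2_right=containing drug0 or"):
            assert feats[name] == 1.0
        # windows are 4 tokens: D2_left starts at "decreased", not "are"
        assert "D2_left=are" not in feats

    def test_drug1_at_start_has_no_left_window(self):
        inst = make_instance("drug1 inhibits drug2 strongly", 0, 2)
        feats = fk.san_features(inst)
        assert not any(n.startswith("D1_left=") for n in feats)


class TestCpn:
    def test_worked_example_conjunctions(self, golden):
        feats = fk.cpn_features(golden)
        for name in (
            "D1_left^D2_left^distance=Plasma^are^5",
            "D1_left^D2_left^distance=Plasma^decreased^5",
            "D1_right^D2_left^distance=are^are^5",
            "D1_left^D2_right^distance=Plasma^containing^5",
            "D1_right^D2_right^distance=are^containing^5",
            "D1_left^D2_right^distance="
            "Plasma concentrations of^containing drug0 or^5",
            "D1_right^D2_left^distance="
            "are decreased when^are decreased when^5",
        ):
            assert feats[name] == 1.0

    def test_adjacent_drugs_emit_only_populated_sides(self):
        inst = make_instance("drug1 drug2 were combined", 0, 1)
        feats = fk.cpn_features(inst)
        # left and inner areas are empty: only D1_right(inner is empty too)
        # -> no D1_left/D1_right conjunctions at all here except right side
        assert all("D2_right" in n or n == "" for n in feats) or feats == {}


class TestExtraFeatures:
    def test_negative_word_detected(self):
        inst = make_instance(
            "interactions between drug1 and drug2 have not been evaluated",
            2, 4)
        assert fk.negative_word_feature(inst) == 1.0

    def test_multiword_negative_entry_matches_consecutively(self):
        inst = make_instance("drug1 fails to affect drug2", 0, 4)
        assert fk.negative_word_feature(inst) == 1.0

    def test_clean_sentence_scores_zero(self, golden):
        assert fk.negative_word_feature(golden) == 0.0

    def test_whole_token_match_only(self):
        inst = make_instance("a notable rise with drug1 and drug2", 4, 6)
        assert fk.negative_word_feature(inst) == 0.0

    def test_name_is_drug_both_specific(self, golden):
        assert fk.name_is_drug_feature(golden) == (-1.0, -1.0)

    def test_name_is_drug_generic_second_entity(self):
        inst = make_instance("drug1 interacts with drug2", 0, 3,
                             e2_surface="drugs")
        assert fk.name_is_drug_feature(inst) == (-1.0, 1.0)

    def test_name_is_drug_both_generic(self):
        inst = make_instance("drug1 interacts with drug2", 0, 3,
                             e1_surface="Drugs", e2_surface="drug")
        assert fk.name_is_drug_feature(inst) == (1.0, 1.0)

    def test_keyword_variant_match_in_inner_area(self, golden):
        feats = fk.keyword_feature(golden)
        assert feats == {"keyword=decrease": 1.0}

    def test_keyword_outside_inner_area_not_emitted(self):
        inst = make_instance("increases of drug1 near drug2 were seen", 2, 4)
        assert fk.keyword_feature(inst) == {}

    def test_semantic_types_sorted_and_joined(self, golden):
        feats = fk.semantic_type_feature(golden)
        assert feats == {"semtype1=carb,phsu": 1.0, "semtype2=gngm": 1.0}

    def test_missing_semtypes_give_empty_vector(self):
        inst = make_instance("drug1 interacts with drug2", 0, 3)
        assert fk.semantic_type_feature(inst) == {}


class TestDrugBank:
    def snapshot(self):
        return fk.DrugBankSnapshot({
            "AlphaDrug": {"indication": "treats severe pain quickly"},
            "BetaDrug": {"indication": "treats severe pain slowly"},
            "GammaDrug": {"indication": "unrelated vocabulary entirely here"},
        })

    def test_identical_bags_flag_one(self):
        snap = self.snapshot()
        assert fk.drugbank_feature("AlphaDrug", "alphadrug", "indication",
                                   snap) == 1.0

    def test_disjoint_bags_flag_zero(self):
        snap = self.snapshot()
        assert fk.drugbank_feature("AlphaDrug", "GammaDrug", "indication",
                                   snap) == 0.0

    def test_cosine_value_matches_direct_formula(self):
        # |V1|=3, |V2|=4, overlap 2 -> 2/sqrt(12) = 0.577 >= 0.4
        snap = fk.DrugBankSnapshot({
            "A": {"indication": "one two three"},
            "B": {"indication": "two three four five"},
        })
        sim = fk.cosine_bag_similarity(snap.bag("A", "indication"),
                                       snap.bag("B", "indication"))
        assert sim == pytest.approx(2 / 12 ** 0.5)
        assert fk.drugbank_feature("A", "B", "indication", snap) == 1.0

    def test_missing_drug_behaves_as_empty_bag(self):
        snap = self.snapshot()
        assert fk.drugbank_feature("NoSuchDrug", "AlphaDrug", "indication",
                                   snap) == 0.0


class TestAssemble:
    def test_worked_example_contains_every_family(self, golden):
        snap = fk.DrugBankSnapshot({})
        vec = fk.assemble_vector(golden, snapshot=snap)
        assert "left_area=Plasma" in vec                      # Abon
        assert "D1_right=are" in vec                          # San
        assert "D1_left^D2_left^distance=Plasma^are^5" in vec  # Cpn
        assert vec["negative_word"] == 0.0
        assert vec["nameisdrug_entity1"] == -1.0
        assert vec["keyword=decrease"] == 1.0
        assert vec["semtype1=carb,phsu"] == 1.0
        assert vec["drugbank_indication"] == 0.0

    def test_deterministic(self, golden):
        assert fk.assemble_vector(golden) == fk.assemble_vector(golden)

    def test_disabling_family_is_pure_ablation(self, golden):
        full = fk.assemble_vector(golden)
        no_cpn = fk.assemble_vector(golden, fk.FeatureConfig(cpn=False))
        assert not any("distance=" in n for n in no_cpn)
        assert {n: v for n, v in full.items() if "distance=" not in n} == no_cpn


def test_lexicons_lowercased_and_deduplicated(tmp_path):
    p = tmp_path / "kw.txt"
    p.write_text("Inhibit\ninhibit\nPOTENTIATE\n\n", encoding="utf-8")
    lex = fk.Lexicons.from_files(keyword_path=p)
    assert lex.keywords == ["inhibit", "potentiate"]
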