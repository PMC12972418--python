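"""Unit and property tests for the free-text annotation module."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitmod.annotation import (
    AnnotationReport,
    Lexicon,
    annotate_conditions,
    annotate_medications,
    detect_negation,
    dl_distance,
    match_token,
    score_window,
    similarity,
    tokenize,
)

from ._oracles import all_strings, osa_distance_recursive, window_score_exhaustive

short_strings = st.text(alphabet="abc", min_size=0, max_size=6)


class TestTokenize:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("Atorvastatin 40mg, Aspirin cardio", ["atorvastatin", "40mg", "aspirin", "cardio"]),
            ("", []),
            ("patient does not take aspirin", ["patient", "does", "not", "take", "aspirin"]),
            ("co-trimoxazol täglich", ["co-trimoxazol", "täglich"]),
        ],
    )
    def test_examples(self, text, expected):
        assert [t.text for t in tokenize(text)] == expected

    def test_spans_point_into_source(self):
        text = "Aspirin; Metformin 500"
        for tok in tokenize(text):
            assert text.casefold()[tok.start : tok.end] == tok.text

    def test_missing_text_is_empty(self):
        assert tokenize(None) == []


class TestDLDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("abc", "abc", 0),
            ("ca", "ac", 1),  # one adjacent transposition
            ("simvastatin", "simvastatine", 1),
            ("", "abc", 3),
            ("kitten", "sitting", 3),
        ],
    )
    def test_known_distances(self, a, b, expected):
        assert dl_distance(a, b) == expected
        assert dl_distance(a, b) == osa_distance_recursive(a, b)

    def test_matches_recursive_oracle_exhaustively_short(self):
        strings = list(all_strings("ab", 4))
        for a in strings:
            for b in strings:
                assert dl_distance(a, b) == osa_distance_recursive(a, b), (a, b)

    @settings(max_examples=200, derandomize=True)
    @given(short_strings, short_strings)
    def test_symmetry_and_identity(self, a, b):
        assert dl_distance(a, b) == dl_distance(b, a)
        assert (dl_distance(a, b) == 0) == (a == b)

    @settings(max_examples=100, derandomize=True)
    @given(short_strings, short_strings, short_strings)
    def test_triangle_inequality(self, a, b, c):
        assert dl_distance(a, c) <= dl_distance(a, b) + dl_distance(b, c)


class TestSimilarity:
    def test_identity_is_one(self):
        assert similarity("atorvastatin", "atorvastatin") == 1.0
        assert similarity("", "") == 1.0

    def test_normalization_by_longer_string(self):
        assert similarity("rosuvastatin", "rosuvastatine") == pytest.approx(1 - 1 / 13)

    def test_dissimilar_drugs_fall_below_threshold(self):
        d = osa_distance_recursive("aspirin", "insulin")
        expected = 1 - d / 7
        assert similarity("aspirin", "insulin") == pytest.approx(expected)
        assert similarity("aspirin", "insulin") < 0.85

    @settings(max_examples=150, derandomize=True)
    @given(short_strings.filter(bool), short_strings.filter(bool))
    def test_symmetric_and_one_iff_equal(self, a, b):
        assert similarity(a, b) == pytest.approx(similarity(b, a))
        assert (similarity(a, b) == 1.0) == (a == b)


class TestMatchToken:
    def test_exact_match(self, mini_drug_lexicon):
        m = match_token("aspirin", mini_drug_lexicon)
        assert m.match_type == "exact" and m.similarity == 1.0 and m.code == "aspirin"

    def test_short_token_requires_exact(self, mini_drug_lexicon):
        # "asa" is one edit from the 3-char lexicon term "ass", but short
        # strings only match exactly
        assert match_token("asa", mini_drug_lexicon) is None
        assert match_token("ass", mini_drug_lexicon).match_type == "exact"

    def test_approximate_match(self, mini_drug_lexicon):
        m = match_token("simvastatine", mini_drug_lexicon)
        assert m.match_type == "approximate"
        assert m.code == "statin"
        assert m.similarity == pytest.approx(1 - 1 / 12)

    def test_number_bearing_tokens_never_match(self, mini_drug_lexicon):
        assert match_token("40mg", mini_drug_lexicon) is None
        assert match_token("aspirin2", mini_drug_lexicon) is None

    def test_below_threshold_is_no_match(self, mini_drug_lexicon):
        assert match_token("paracetamol", mini_drug_lexicon) is None

    def test_tie_break_prefers_longer_term_then_code(self):
        lex = Lexicon.from_pairs(
            [("abcdx", "z_code", "drug-generic"), ("abcdxy", "a_code", "drug-generic")]
        )
        # "abcdxz" has distance 1 to both terms but max-length 6 for both
        # -> equal similarity; the longer term wins
        m = match_token("abcdxz", lex, threshold=0.5)
        assert m.matched_term == "abcdxy" and m.code == "a_code"
        lex2 = Lexicon.from_pairs(
            [("abcde", "z_code", "drug-generic"), ("abcdf", "a_code", "drug-generic")]
        )
        m2 = match_token("abcdg", lex2, threshold=0.5)
        assert m2.code == "a_code"  # equal similarity and length: smaller code

    def test_threshold_validation(self, mini_drug_lexicon):
        with pytest.raises(ValueError):
            match_token("aspirin", mini_drug_lexicon, threshold=0.0)


class TestNegation:
    def test_paper_style_example(self):
        toks = tokenize("patient does not take aspirin")
        assert detect_negation(toks, (4, 5)) is True

    def test_unnegated(self):
        toks = tokenize("takes aspirin daily")
        assert detect_negation(toks, (1, 2)) is False

    def test_window_boundary(self):
        # cue exactly window+1 tokens before the span is out of scope
        toks = tokenize("not a b c aspirin")
        assert detect_negation(toks, (4, 5), window=3) is False
        assert detect_negation(toks, (4, 5), window=4) is True

    def test_german_cue(self):
        toks = tokenize("nimmt kein metformin")
        assert detect_negation(toks, (2, 3)) is True


class TestAnnotateMedications:
    def test_two_exact_matches(self, mini_drug_lexicon):
        rep = annotate_medications("Atorvastatin 40mg, Bisoprolol", mini_drug_lexicon)
        assert rep.codes == {"statin", "beta_blocker"}
        assert rep.n_exact == 2 and rep.n_negated == 0

    def test_negation_suppresses_and_typo_recovers(self, mini_drug_lexicon):
        rep = annotate_medications(
            "patient does not take aspirin; Metformine 500", mini_drug_lexicon
        )
        assert rep.codes == {"biguanide"}
        assert rep.n_negated == 1
        assert rep.n_approximate == 1  # metformine -> metformin, sim 0.9

    def test_missing_text_marks_exclusion(self, mini_drug_lexicon):
        for text in (None, "", "   "):
            rep = annotate_medications(text, mini_drug_lexicon)
            assert rep.excluded and not rep.codes

    def test_brand_name_maps_to_class(self, mini_drug_lexicon):
        rep = annotate_medications("Lipitor 20mg", mini_drug_lexicon)
        assert rep.codes == {"statin"}

    def test_no_accepted_code_from_negated_span(self, mini_drug_lexicon):
        rep = annotate_medications(
            "no aspirin, stopped simvastatin, metformin", mini_drug_lexicon
        )
        assert rep.codes == {"biguanide"}
        for m in rep.matches:
            if m.negated:
                assert m.code not in rep.codes or any(
                    not m2.negated and m2.code == m.code for m2 in rep.matches
                )


@pytest.fixture(scope="module")
def chd_lexicon():
    return Lexicon.from_pairs(
        [
            ("coronary heart disease", "coronary_heart_disease", "en"),
            ("hypertension", "hypertension", "en"),
            ("bluthochdruck", "hypertension", "de"),
        ]
    )


class TestAnnotateConditions:
    def test_exact_multitoken_inside_window(self, chd_lexicon):
        rep = annotate_conditions("known coronary heart disease since 2015", chd_lexicon)
        assert "coronary_heart_disease" in rep.codes

    def test_tolerates_interleaved_word(self, chd_lexicon):
        # window = 3 tokens + 2 allows one extra word inside the description
        rep = annotate_conditions("coronary ischemic heart disease", chd_lexicon)
        assert "coronary_heart_disease" in rep.codes

    def test_agrees_with_exhaustive_window_oracle(self, chd_lexicon):
        texts = [
            "coronary artery disease",
            "known coronary heart disease",
            "severe hypertension and diabetes",
            "heart disease",
            "coronarx heart diseasx since 2001",
        ]
        for text in texts:
            toks = [t.text for t in tokenize(text)]
            oracle = window_score_exhaustive("coronary heart disease", toks, 0.85)
            rep = annotate_conditions(text, chd_lexicon)
            assert ("coronary_heart_disease" in rep.codes) == (oracle >= 0.85), text

    def test_score_window_matches_oracle_value(self):
        toks = ["coronary", "artery", "disease"]
        got = score_window("coronary heart disease".split(), toks)
        want = window_score_exhaustive("coronary heart disease", toks, 0.0)
        assert got == pytest.approx(want)

    def test_german_term(self, chd_lexicon):
        rep = annotate_conditions("bekannter Bluthochdruck", chd_lexicon)
        assert rep.codes == {"hypertension"}

    def test_negated_condition_not_flagged(self, chd_lexicon):
        rep = annotate_conditions("kein bluthochdruck", chd_lexicon)
        assert "hypertension" not in rep.codes

    def test_missing_history_yields_empty_report(self, chd_lexicon):
        rep = annotate_conditions(None, chd_lexicon)
        assert isinstance(rep, AnnotationReport) and not rep.codes and not rep.excluded


class TestLexicon:
    def test_duplicate_terms_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Lexicon.from_pairs(
                [("aspirin", "a", "drug-generic"), ("Aspirin ", "b", "drug-generic")]
            )

    def test_csv_round_trip(self, tmp_path, mini_drug_lexicon):
        path = tmp_path / "lex.csv"
        mini_drug_lexicon.to_csv(path)
        loaded = Lexicon.from_csv(path)
        assert {e.term for e in loaded.entries} == {e.term for e in mini_drug_lexicon.entries}
        assert loaded.codes == mini_drug_lexicon.codes
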