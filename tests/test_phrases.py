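"""Phrase-stage behavior: categorization, matching, rendering, ruleset IO."""

import pytest

from ftnorm.phrases import (CategorySequence, PhraseType, categorize,
                            load_phrase_types, match_phrase_type,
                            normalize_phrase, render_standard_form,
                            write_phrase_types)
from ftnorm.rules import RuleStore
from ftnorm.words import tokenize


class TestCategorize:
    def test_statistical_example(self, age_word_store):
        seq = categorize("6 week mean", age_word_store)
        assert seq.serialize() == "[number(0)][unit(1)][statistical(2)]"

    def test_range_example(self, age_word_store):
        seq = categorize("6 to 8 week", age_word_store)
        assert seq.serialize() == \
            "[number(0)][range_indicator(1)][number(2)][unit(3)]"

    def test_uncategorized_word_is_unknown(self):
        seq = categorize("zzz", RuleStore("word"))
        assert seq.serialize() == "[unknown(0)]"

    def test_atoms_get_intrinsic_categories(self, loc_word_store):
        seq = categorize("[Fig F1] https://x.org/a", loc_word_store)
        assert seq.labels() == ("bracketed_ref", "url")

    def test_indices_match_token_ordinals(self, age_word_store):
        seq = categorize("mean: 30 year", age_word_store)
        assert [i for _, i in seq.entries] == [0, 1, 2]


class TestSerialization:
    def test_parse_round_trip(self):
        text = "[number(0)][unit(1)][statistical(2)]"
        assert CategorySequence.parse(text).serialize() == text

    def test_unparsable_rejected(self):
        with pytest.raises(ValueError):
            CategorySequence.parse("[number(0)] [unit(1)]")  # stray space


class TestMatch:
    def test_table_patterns(self, age_phrase_ruleset):
        seq = CategorySequence.parse("[statistical(0)][number(1)][unit(2)]")
        assert match_phrase_type(seq, age_phrase_ruleset).name == "statistical"

    def test_pdb_pattern(self, loc_phrase_ruleset):
        seq = CategorySequence.parse("[pdb(0)][pdb_id(1)]")
        assert match_phrase_type(seq, loc_phrase_ruleset).name == "pdb id"

    def test_no_match_is_none(self, age_phrase_ruleset):
        seq = CategorySequence.parse("[unknown(0)]")
        assert match_phrase_type(seq, age_phrase_ruleset) is None

    def test_first_in_file_order_wins(self):
        ruleset = [PhraseType("a", ("number",), True, "[0]"),
                   PhraseType("b", ("number",), False, "[0]")]
        seq = CategorySequence.parse("[number(0)]")
        assert match_phrase_type(seq, ruleset).name == "a"


class TestRender:
    @pytest.mark.parametrize("template,text,expected", [
        ("[2]: [0] [1]", "6 week mean", "mean: 6 week"),
        ("[0]-[2] [3]", "6 to 8-week", "6-8 week"),
        ("[0] [1]", "page 11782", "page 11782"),
    ])
    def test_examples(self, template, text, expected):
        tokens = tokenize(text)
        pt = PhraseType("t", tuple("x" for _ in tokens), True, template)
        assert render_standard_form(pt, tokens) == expected

    def test_out_of_range_placeholder_names_pattern(self):
        with pytest.raises(ValueError, match="broken"):
            pt = PhraseType.__new__(PhraseType)  # bypass validation
            object.__setattr__(pt, "name", "broken")
            object.__setattr__(pt, "pattern", ("number",))
            object.__setattr__(pt, "valid", True)
            object.__setattr__(pt, "standard_form", "[5]")
            render_standard_form(pt, tokenize("6"))

    def test_placeholder_validation_at_construction(self):
        with pytest.raises(ValueError):
            PhraseType("bad", ("number",), True, "[3]")


class TestNormalizePhrase:
    def test_valid_match_renders(self, age_word_store, age_phrase_ruleset):
        res = normalize_phrase("median 6.3 year", age_word_store,
                               age_phrase_ruleset)
        assert res.text_out == "median: 6.3 year" and res.valid == "pass"

    def test_invalid_pattern_distinct_from_no_match(self, age_word_store,
                                                    age_phrase_ruleset):
        bare_range = normalize_phrase("8-10", age_word_store, age_phrase_ruleset)
        assert bare_range.valid == "fail_invalid_pattern"
        assert bare_range.text_out == "8-10"  # invalid: not rewritten
        bare_number = normalize_phrase("7", age_word_store, age_phrase_ruleset)
        assert bare_number.valid == "fail_invalid_pattern"
        no_match = normalize_phrase("zzz", age_word_store, age_phrase_ruleset)
        assert no_match.valid == "fail_no_match"
        assert no_match.text_out == "zzz"

    def test_categorization_recorded_for_every_item(self, age_word_store,
                                                    age_phrase_ruleset):
        for text in ("6 week", "zzz", "8-10"):
            res = normalize_phrase(text, age_word_store, age_phrase_ruleset)
            assert res.categorization

    def test_idempotent_on_standard_forms(self, age_word_store,
                                          age_phrase_ruleset):
        # the bundled ruleset maps its own standard forms to themselves
        for text in ("6 week", "6-8 week", "mean: 30 year"):
            once = normalize_phrase(text, age_word_store, age_phrase_ruleset)
            twice = normalize_phrase(once.text_out, age_word_store,
                                     age_phrase_ruleset)
            assert twice.text_out == once.text_out


class TestRulesetIO:
    def test_round_trip(self, tmp_path, age_phrase_ruleset):
        path = tmp_path / "pt.tsv"
        write_phrase_types(age_phrase_ruleset, path)
        assert load_phrase_types(path) == age_phrase_ruleset

    def test_absent_file_is_empty_ruleset(self, tmp_path):
        assert load_phrase_types(tmp_path / "missing.tsv") == []

    def test_unparsable_pattern_names_row(self, tmp_path):
        path = tmp_path / "pt.tsv"
        path.write_text("name\tpattern\tvalid\tstandard_form\n"
                        "bad\tnumber unit\ttrue\t[0]\n")
        with pytest.raises(ValueError, match="2"):
            load_phrase_types(path)

    def test_duplicate_pattern_logs_warning(self, tmp_path, caplog):
        path = tmp_path / "pt.tsv"
        path.write_text("name\tpattern\tvalid\tstandard_form\n"
                        "a\t[number(0)]\ttrue\t[0]\n"
                        "b\t[number(0)]\tfalse\t[0]\n")
        with caplog.at_level("WARNING"):
            ruleset = load_phrase_types(path)
        assert len(ruleset) == 2
        assert any("share a pattern" in r.message for r in caplog.records)
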