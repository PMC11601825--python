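"""Rule bank behavior: decisions, promotion, inventory, TSV round-trips."""

import pytest

from ftnorm.rules import (ActionDecision, RuleRow, RuleStore, load_rulestore,
                          write_rulestore)


def make_store():
    return RuleStore(
        "word",
        rows=[RuleRow("old", ["6-10 week old"], 710),
              RuleRow("undecided", ["context"], 3)],
        reference_rows=[
            RuleRow("wk", ["8-10 wk"], 57,
                    decision=ActionDecision("replace_with", "week")),
            RuleRow("week", ["6 week"], 640,
                    decision=ActionDecision("allow"), category="unit"),
        ],
    )


class TestActionDecision:
    def test_replace_requires_replacement(self):
        with pytest.raises(ValueError):
            ActionDecision("replace_with")

    def test_non_replace_rejects_replacement(self):
        with pytest.raises(ValueError):
            ActionDecision("remove", "x")

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            ActionDecision("delete")


class TestPromotion:
    def test_decided_rows_move_and_nothing_is_lost(self):
        store = make_store()
        store.review["old"].decision = ActionDecision("remove")
        before_units = store.units()
        store.promote_decided()
        assert "old" in store.reference and "old" not in store.review
        assert "undecided" in store.review
        assert store.units() == before_units

    def test_idempotent(self):
        store = make_store()
        store.review["old"].decision = ActionDecision("remove")
        store.promote_decided()
        ref_once = dict(store.reference)
        rev_once = dict(store.review)
        store.promote_decided()
        assert store.reference == ref_once and store.review == rev_once

    def test_no_decided_rows_is_identity(self):
        store = make_store()
        review, reference = dict(store.review), dict(store.reference)
        store.promote_decided()
        assert store.review == review and store.reference == reference


class TestRecordNewUnits:
    def test_new_unit_lands_in_review(self):
        store = make_store()
        store.record_new_units({"new": (10, ["a new context"])})
        assert store.review["new"].count == 10
        assert store.review["new"].decision is None

    def test_reference_unit_not_duplicated_and_decision_untouched(self):
        store = make_store()
        store.record_new_units({"wk": (60, ["8-10 wk", "1 wk"])})
        assert "wk" not in store.review
        assert store.reference["wk"].count == 60  # count refreshed
        assert store.reference["wk"].decision.kind == "replace_with"

    def test_empty_inventory_is_identity(self):
        store = make_store()
        review, reference = dict(store.review), dict(store.reference)
        store.record_new_units({})
        assert store.review == review and store.reference == reference

    def test_context_cap(self):
        store = make_store()
        store.record_new_units({"x": (9, [f"ctx{i}" for i in range(9)])},
                               context_cap=5)
        assert len(store.review["x"].contexts) == 5


class TestDecide:
    def test_decide_then_promote_applies(self):
        store = make_store()
        store.decide("old", "remove")
        store.promote_decided()
        assert store.decision_for("old").kind == "remove"

    def test_unknown_unit(self):
        with pytest.raises(KeyError):
            make_store().decide("nope", "allow")

    def test_existing_decision_needs_force(self):
        store = make_store()
        with pytest.raises(ValueError):
            store.decide("wk", "allow")
        store.decide("wk", "allow", force=True)
        assert store.lookup("wk").decision.kind == "allow"


class TestRoundTrip:
    def test_lossless(self, tmp_path):
        store = make_store()
        write_rulestore(store, tmp_path / "rev.tsv", tmp_path / "ref.tsv")
        again = load_rulestore(tmp_path / "rev.tsv", tmp_path / "ref.tsv", "word")
        assert again == store

    def test_unicode_unit_survives(self, tmp_path):
        store = RuleStore("character", reference_rows=[
            RuleRow("–", ["20–67 years"], 31,
                    decision=ActionDecision("replace_with", "-"))])
        write_rulestore(store, tmp_path / "rev.tsv", tmp_path / "ref.tsv")
        again = load_rulestore(tmp_path / "rev.tsv", tmp_path / "ref.tsv",
                               "character")
        row = again.reference["–"]
        assert row.decision.replacement == "-" and row.count == 31

    def test_empty_store_writes_header_only(self, tmp_path):
        write_rulestore(RuleStore("word"), tmp_path / "rev.tsv",
                        tmp_path / "ref.tsv")
        lines = (tmp_path / "rev.tsv").read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("unit\t")
        assert load_rulestore(tmp_path / "rev.tsv", tmp_path / "ref.tsv",
                              "word").units() == set()

    def test_absent_files_mean_empty_banks(self, tmp_path):
        store = load_rulestore(tmp_path / "nope.tsv", tmp_path / "nada.tsv",
                               "word")
        assert store.units() == set()


class TestLoadErrors:
    def test_duplicate_unit_across_files(self, tmp_path):
        header = "unit\tcontext\tcount\treplace_with\tremove\tinvalidate\tallow\tcategory\n"
        (tmp_path / "rev.tsv").write_text(header + "old\tctx\t1\t\t\t\t\t\n")
        (tmp_path / "ref.tsv").write_text(header + "old\tctx\t1\t\tx\t\t\t\n")
        with pytest.raises(ValueError, match="old"):
            load_rulestore(tmp_path / "rev.tsv", tmp_path / "ref.tsv", "word")

    def test_two_actions_on_one_row(self, tmp_path):
        header = "unit\tcontext\tcount\treplace_with\tremove\tinvalidate\tallow\tcategory\n"
        (tmp_path / "rev.tsv").write_text(header + "old\tctx\t1\t\tx\t\tx\t\n")
        with pytest.raises(ValueError, match="2"):
            load_rulestore(tmp_path / "rev.tsv", None, "word")

    def test_category_rejected_on_character_rows(self):
        with pytest.raises(ValueError):
            RuleStore("character", rows=[RuleRow("x", category="unit")])


def test_unit_uniqueness_invariant_after_operations():
    store = make_store()
    store.record_new_units({"fresh": (1, [])})
    store.decide("fresh", "allow")
    store.promote_decided()
    assert set(store.review) & set(store.reference) == set()
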