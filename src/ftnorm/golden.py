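"""Worked examples and bundled fixture rulesets.

The package ships small reconstructed rule banks for two field types it was
developed against — subject *age* values and publication *data-location*
values — together with the published worked examples those rules reproduce.
The banks cover the printed sample rules plus the handful of extra rules
the end-to-end examples require; they are fixtures for tests and demos, not
a complete curation of either field.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .phrases import PhraseType, load_phrase_types
from .rules import RuleStore, load_rulestore

__all__ = [
    "GoldenExample",
    "golden_examples",
    "bundled_rulestore",
    "bundled_phrase_types",
    "bundled_path",
]

DATASETS = ("age", "data_location")


def bundled_path(name: str) -> Path:
    """Filesystem path of a bundled data file (e.g. ``age_word_reference.tsv``)."""
    return Path(resources.files("ftnorm.data") / name)


def bundled_rulestore(dataset: str, level: str) -> RuleStore:
    """Load the bundled reference bank for a dataset at one level."""
    if dataset not in DATASETS:
        raise ValueError(f"unknown dataset {dataset!r}")
    short = "char" if level == "character" else "word"
    return load_rulestore(None, bundled_path(f"{dataset}_{short}_reference.tsv"), level)


def bundled_phrase_types(dataset: str) -> list[PhraseType]:
    if dataset not in DATASETS:
        raise ValueError(f"unknown dataset {dataset!r}")
    return load_phrase_types(bundled_path(f"{dataset}_phrase_types.tsv"))


@dataclass(frozen=True)
class GoldenExample:
    """One published worked example with expected outputs per stage.

    ``None`` for a stage means the example does not constrain it.  For
    list-like data-location items ``segments`` holds the expected post-split
    phrase outputs in order.
    """

    dataset: str
    source: str  # which published table/example the row comes from
    raw: str
    char_expected: str | None = None
    char_verdict: str = "pass"
    word_input: str | None = None  # for word-only examples
    word_expected: str | None = None
    phrase_input: str | None = None  # for phrase-only examples
    phrase_expected: str | None = None
    segments: tuple[str, ...] | None = None


def golden_examples() -> list[GoldenExample]:
    """Every published worked example, tagged with its table of origin."""
    g = GoldenExample
    return [
        # --- sample character rules in application -----------------------
        g("age", "char-rules", raw="mean age = 30 years",
          char_expected="mean age = 30 years"),
        g("age", "char-rules", raw="20–67 years",
          char_expected="20-67 years"),
        g("data_location", "char-rules", raw="Abstract & p. 664",
          char_expected="abstract and p. 664"),
        g("data_location", "char-rules",
          raw="[Fig F1] and [Fig F1]â€”figure supplement 1 and PDB 6HD8",
          char_expected="[Fig F1] and [Fig F1]â€”figure supplement 1 and PDB 6HD8",
          char_verdict="fail_invalidated"),
        # --- sample word rules in application ----------------------------
        g("age", "word-rules", raw="6-10 week old",
          word_input="6-10 week old", word_expected="6-10 week"),
        g("age", "word-rules", raw="8-10 wk",
          word_input="8-10 wk", word_expected="8-10 week"),
        g("data_location", "word-rules", raw="[Fig F1] and [Fig F2]",
          word_input="[Fig F1] and [Fig F2]",
          word_expected="[Fig F1] and [Fig F2]"),
        g("data_location", "word-rules", raw="additional file 1",
          word_input="additional file 1", word_expected="additional file 1"),
        # --- sample phrase rules in application --------------------------
        g("age", "phrase-rules", raw="6 to 8-week",
          phrase_input="6 to 8-week", phrase_expected="6-8 week"),
        g("age", "phrase-rules", raw="44.9 to 74.1 year",
          phrase_input="44.9 to 74.1 year", phrase_expected="44.9-74.1 year"),
        g("age", "phrase-rules", raw="36 to 68.2 year",
          phrase_input="36 to 68.2 year", phrase_expected="36-68.2 year"),
        g("age", "phrase-rules", raw="mean 29.8 year",
          phrase_input="mean 29.8 year", phrase_expected="mean: 29.8 year"),
        g("age", "phrase-rules", raw="mean: 30 year",
          phrase_input="mean: 30 year", phrase_expected="mean: 30 year"),
        g("age", "phrase-rules", raw="median : 7.5 year",
          phrase_input="median : 7.5 year", phrase_expected="median: 7.5 year"),
        g("age", "phrase-rules", raw="6 week mean",
          phrase_input="6 week mean", phrase_expected="mean: 6 week"),
        g("data_location", "phrase-rules", raw="pdb 1mfd",
          phrase_input="pdb 1mfd", phrase_expected="pdb 1mfd"),
        g("data_location", "phrase-rules", raw="pdb 1rzj",
          phrase_input="pdb 1rzj", phrase_expected="pdb 1rzj"),
        g("data_location", "phrase-rules", raw="pdb 1rzk",
          phrase_input="pdb 1rzk", phrase_expected="pdb 1rzk"),
        g("data_location", "phrase-rules", raw="page 11782",
          phrase_input="page 11782", phrase_expected="page 11782"),
        g("data_location", "phrase-rules", raw="information 9",
          phrase_input="information 9", phrase_expected="information 9"),
        g("data_location", "phrase-rules", raw="data 1",
          phrase_input="data 1", phrase_expected="data 1"),
        # --- end-to-end sample items -------------------------------------
        g("age", "end-to-end", raw="Six week old",
          char_expected="six week old", word_expected="6 week",
          phrase_expected="6 week"),
        g("age", "end-to-end", raw="6 to 8-week old",
          char_expected="6 to 8-week old", word_expected="6 to 8-week",
          phrase_expected="6-8 week"),
        g("age", "end-to-end", raw="Median age 6.3 years",
          char_expected="median age 6.3 years", word_expected="median 6.3 year",
          phrase_expected="median: 6.3 year"),
        g("data_location", "end-to-end",
          raw="Additional File 4,[Table T1] and [Table T2]",
          char_expected="additional file 4,[Table T1] and [Table T2]",
          segments=("additional file 4", "[Table T1]", "[Table T2]")),
        g("data_location", "end-to-end",
          raw="[Fig F2],[Fig F2],[Fig F2], Fig. 6.",
          char_expected="[Fig F2],[Fig F2],[Fig F2], fig. 6.",
          segments=("[Fig F2]", "[Fig F2]", "[Fig F2]", "figure 6")),
        g("data_location", "end-to-end",
          raw="[Fig F2],[Fig F2], Suppl Fig. 2",
          char_expected="[Fig F2],[Fig F2], suppl fig. 2",
          segments=("[Fig F2]", "[Fig F2]", "supplemental figure 2")),
        # --- split-count examples ----------------------------------------
        g("data_location", "split-counts", raw="[Table T1] and [Fig F1]",
          segments=("[Table T1]", "[Fig F1]")),
        g("data_location", "split-counts",
          raw="[Table T4] and [Fig F1] and [Fig F2] and Supporting Information S2 Figure",
          segments=("[Table T4]", "[Fig F1]", "[Fig F2]",
                    "supporting information s2 figure")),
        g("data_location", "split-counts",
          raw="[Fig F1], [Fig F2], [Fig F3], [Fig F4], Supplementary Figs. "
              "2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13",
          segments=("[Fig F1]", "[Fig F2]", "[Fig F3]", "[Fig F4]")
                   + tuple(f"supplementary figure {n}" for n in range(2, 14))),
    ]
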