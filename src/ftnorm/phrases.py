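"""Phrase-stage categorization, pattern matching, and template rewriting.

Each word-valid item is turned into a *categorization string*: one
``[label(index)]`` entry per token, with the label drawn from the word
bank's category column, ``number`` for numeric tokens, ``bracketed_ref`` /
``url`` for protected atoms, and ``unknown`` otherwise.  The sequence of
labels is matched exactly against a curator-authored phrase-type ruleset;
a match to a valid pattern rewrites the item into that pattern's standard
form, a template whose ``[i]`` placeholders pull in the i-th token's text.
Items matching an invalid pattern, or no pattern, keep their word-stage
text.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .atoms import is_bracketed, is_url
from .rules import RuleStore
from .words import Token, is_numeric, tokenize

__all__ = [
    "CategorySequence",
    "PhraseType",
    "PhraseResult",
    "categorize",
    "match_phrase_type",
    "render_standard_form",
    "normalize_phrase",
    "load_phrase_types",
    "write_phrase_types",
]

logger = logging.getLogger(__name__)

_ENTRY_RE = re.compile(r"\[([^\[\]()]+)\((\d+)\)\]")
_PLACEHOLDER_RE = re.compile(r"\[(\d+)\]")


@dataclass(frozen=True)
class CategorySequence:
    """Ordered (label, index) pairs; serializes as ``[label(0)][label(1)]...``."""

    entries: tuple[tuple[str, int], ...]

    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.entries)

    def serialize(self) -> str:
        return "".join(f"[{label}({i})]" for label, i in self.entries)

    @classmethod
    def parse(cls, text: str) -> "CategorySequence":
        entries = [(m.group(1), int(m.group(2))) for m in _ENTRY_RE.finditer(text)]
        rebuilt = "".join(f"[{l}({i})]" for l, i in entries)
        if rebuilt != text:
            raise ValueError(f"unparsable categorization string: {text!r}")
        return cls(entries=tuple(entries))


@dataclass(frozen=True)
class PhraseType:
    """A named category-sequence pattern with validity flag and template."""

    name: str
    pattern: tuple[str, ...]
    valid: bool
    standard_form: str

    def __post_init__(self) -> None:
        for m in _PLACEHOLDER_RE.finditer(self.standard_form):
            if int(m.group(1)) >= len(self.pattern):
                raise ValueError(
                    f"phrase type {self.name!r}: placeholder [{m.group(1)}] "
                    f"exceeds pattern length {len(self.pattern)}"
                )


@dataclass(frozen=True)
class PhraseResult:
    text_out: str
    matched_pattern: str | None
    valid: str  # pass | fail_invalid_pattern | fail_no_match
    categorization: str


def _token_category(token: Token, word_store: RuleStore) -> str:
    if is_bracketed(token.text):
        return "bracketed_ref"
    if is_url(token.text):
        return "url"
    if is_numeric(token.text):
        return "number"
    return word_store.category_for(token.text) or "unknown"


def categorize(text: str, word_store: RuleStore) -> CategorySequence:
    """Label each token of a word-normalized item by its category."""
    entries = tuple((_token_category(t, word_store), t.index) for t in tokenize(text))
    return CategorySequence(entries=entries)


def match_phrase_type(seq: CategorySequence,
                      ruleset: Sequence[PhraseType]) -> PhraseType | None:
    """First phrase type (file order) whose pattern equals the labels exactly."""
    labels = seq.labels()
    for pt in ruleset:
        if pt.pattern == labels:
            return pt
    return None


def render_standard_form(pt: PhraseType, tokens: Sequence[Token]) -> str:
    """Fill the template's ``[i]`` placeholders with token texts."""

    def _sub(match: re.Match) -> str:
        i = int(match.group(1))
        if i >= len(tokens):
            raise ValueError(
                f"phrase type {pt.name!r}: placeholder [{i}] out of range "
                f"for {len(tokens)} tokens"
            )
        return tokens[i].text

    return _PLACEHOLDER_RE.sub(_sub, pt.standard_form)


def normalize_phrase(text: str, word_store: RuleStore,
                     ruleset: Sequence[PhraseType]) -> PhraseResult:
    """Categorize, match, and (for valid matches) rewrite one item."""
    seq = categorize(text, word_store)
    pt = match_phrase_type(seq, ruleset)
    if pt is None:
        return PhraseResult(text_out=text, matched_pattern=None,
                            valid="fail_no_match", categorization=seq.serialize())
    if not pt.valid:
        return PhraseResult(text_out=text, matched_pattern=pt.name,
                            valid="fail_invalid_pattern",
                            categorization=seq.serialize())
    rendered = render_standard_form(pt, tokenize(text))
    return PhraseResult(text_out=rendered, matched_pattern=pt.name,
                        valid="pass", categorization=seq.serialize())


# -- ruleset input/output ------------------------------------------------

_COLUMNS = ["name", "pattern", "valid", "standard_form"]


def _parse_pattern(text: str, path: Path, lineno: int) -> tuple[str, ...]:
    try:
        seq = CategorySequence.parse(text)
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return seq.labels()


def load_phrase_types(path: str | Path) -> list[PhraseType]:
    """Load a phrase-type ruleset TSV; an absent file is an empty ruleset.

    Duplicate label sequences are legal but logged (first in file order
    wins); duplicate names are a hard error.
    """
    path = Path(path)
    if not path.exists():
        return []
    ruleset: list[PhraseType] = []
    names: set[str] = set()
    seen_patterns: dict[tuple[str, ...], str] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t", quoting=csv.QUOTE_NONE)
        for lineno, record in enumerate(reader, start=2):
            name = record.get("name", "")
            if not name:
                raise ValueError(f"{path}:{lineno}: empty phrase-type name")
            if name in names:
                raise ValueError(f"{path}:{lineno}: duplicate phrase-type name {name!r}")
            names.add(name)
            pattern = _parse_pattern(record.get("pattern", ""), path, lineno)
            if pattern in seen_patterns:
                logger.warning(
                    "phrase types %r and %r share a pattern; %r wins (file order)",
                    seen_patterns[pattern], name, seen_patterns[pattern])
            else:
                seen_patterns[pattern] = name
            valid = record.get("valid", "").strip().lower() in ("true", "1", "yes")
            ruleset.append(PhraseType(name=name, pattern=pattern, valid=valid,
                                      standard_form=record.get("standard_form", "")))
    return ruleset


def write_phrase_types(ruleset: Iterable[PhraseType], path: str | Path) -> None:
    """Write a ruleset as unquoted TSV; load(write(rs)) == rs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_COLUMNS, delimiter="\t",
                                quoting=csv.QUOTE_NONE, quotechar=None,
                                lineterminator="\n")
        writer.writeheader()
        for pt in ruleset:
            pattern = "".join(f"[{label}({i})]" for i, label in enumerate(pt.pattern))
            writer.writerow({
                "name": pt.name,
                "pattern": pattern,
                "valid": "true" if pt.valid else "false",
                "standard_form": pt.standard_form,
            })
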