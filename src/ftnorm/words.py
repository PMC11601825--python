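"""Word-stage tokenization and normalization.

A word is a maximal run of characters between delimiters (spaces, hyphens,
and common punctuation), with two exceptions: a decimal point flanked by
digits stays inside its number token ("6.3" is one word), and protected
atoms (URLs, bracketed reference spans) are single tokens exempt from word
rules.  Tokens carry their surrounding delimiter runs so the original
string can be reconstructed exactly, and so removal can merge delimiters
cleanly.

Word rules come from the word rule bank: replace a token wholesale, remove
it, invalidate the whole item, or allow it.  Numeric tokens and atoms are
intrinsically allowed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

from .atoms import ATOM_RE, is_atom, is_bracketed, is_url
from .metrics import levenshtein
from .rules import RuleStore

__all__ = [
    "Token",
    "WordStageResult",
    "tokenize",
    "is_numeric",
    "inventory_words",
    "normalize_words",
]

#: delimiter characters separating words
DELIMITERS = " -,.:;()/="

_NUMBER_RE = re.compile(r"\d+(?:\.\d+)?")
# a token: an atom, or a run of non-delimiters where "." between digits
# does not break the run
_TOKEN_RE = re.compile(
    ATOM_RE.pattern + r"|(?:[^ \-,.:;()/=]|(?<=\d)\.(?=\d))+"
)


def is_numeric(text: str) -> bool:
    """True for digit runs with at most one decimal point ("6", "6.3")."""
    return _NUMBER_RE.fullmatch(text) is not None


@dataclass(frozen=True)
class Token:
    """One word with its position and flanking delimiter runs.

    ``lead_delim + text`` concatenated over all tokens, plus the last
    token's ``trail_delim``, reconstructs the source string exactly.
    """

    text: str
    index: int
    lead_delim: str = ""
    trail_delim: str = ""


def tokenize(text: str) -> list[Token]:
    """Split char-normalized text into tokens with delimiter bookkeeping."""
    tokens: list[Token] = []
    matches = list(_TOKEN_RE.finditer(text))
    for i, match in enumerate(matches):
        lead_start = matches[i - 1].end() if i else 0
        trail_end = matches[i + 1].start() if i + 1 < len(matches) else len(text)
        tokens.append(Token(
            text=match.group(),
            index=i,
            lead_delim=text[lead_start:match.start()],
            trail_delim=text[match.end():trail_end],
        ))
    return tokens


def reconstruct(tokens: list[Token]) -> str:
    if not tokens:
        return ""
    return "".join(t.lead_delim + t.text for t in tokens) + tokens[-1].trail_delim


@dataclass(frozen=True)
class WordStageResult:
    text_out: str
    valid: str  # pass | fail_invalidated | fail_unknown_unit
    distance: int


def inventory_words(items: Iterable[str], store: RuleStore,
                    context_cap: int = 5) -> RuleStore:
    """Record distinct token texts from char-valid items into review.

    Numeric tokens and protected atoms are intrinsically allowed and are
    not inventoried.
    """
    if store.level != "word":
        raise ValueError("inventory_words requires a word-level store")
    counts: dict[str, int] = {}
    contexts: dict[str, list[str]] = {}
    for item in items:
        seen_here: set[str] = set()
        for token in tokenize(item):
            word = token.text
            if is_numeric(word) or is_atom(word):
                continue
            counts[word] = counts.get(word, 0) + 1
            if word not in seen_here and len(contexts.setdefault(word, [])) < context_cap:
                contexts[word].append(item)
            seen_here.add(word)
    inventory = {w: (counts[w], contexts.get(w, [])) for w in counts}
    return store.record_new_units(inventory, context_cap=context_cap)


def _token_allowed(word: str, store: RuleStore, from_replace: bool) -> bool:
    if is_numeric(word) or is_atom(word):
        return True
    if from_replace:
        # produced by a curator's replace rule: accepted as normalized
        return True
    decision = store.decision_for(word)
    return decision is not None and decision.kind in ("allow", "replace_with")


def normalize_words(text: str, store: RuleStore) -> WordStageResult:
    """Apply the word bank to one char-normalized item and validate.

    Invalidate rules are checked first and leave the item untouched.
    Replacement substitutes the whole token; removal drops the token and
    keeps its leading delimiter run, after which doubled spaces collapse
    and the ends are trimmed.  Validation requires every surviving token to
    be allowed, numeric, an atom, or the product of a replace rule.
    """
    if store.level != "word":
        raise ValueError("normalize_words requires a word-level store")
    tokens = tokenize(text)

    for token in tokens:
        if is_atom(token.text):
            continue
        decision = store.decision_for(token.text)
        if decision is not None and decision.kind == "invalidate":
            return WordStageResult(text_out=text, valid="fail_invalidated", distance=0)

    parts: list[str] = []
    replaced: set[str] = set()
    pending_delim = ""
    for i, token in enumerate(tokens):
        lead = pending_delim or token.lead_delim
        pending_delim = ""
        word = token.text
        if not is_atom(word):
            decision = store.decision_for(word)
            if decision is not None:
                if decision.kind == "replace_with":
                    replaced.add(decision.replacement or "")
                    word = decision.replacement or ""
                elif decision.kind == "remove":
                    # keep the leading delimiter run for the next token
                    pending_delim = lead if lead else token.trail_delim
                    continue
        parts.append(lead + word)
    trail = tokens[-1].trail_delim if tokens else ""
    text_out = "".join(parts) + (pending_delim if not parts else "") + trail
    text_out = re.sub(r"  +", " ", text_out).strip()

    valid = "pass"
    for token in tokenize(text_out):
        if not _token_allowed(token.text, store, token.text in replaced):
            valid = "fail_unknown_unit"
            break

    return WordStageResult(text_out=text_out, valid=valid,
                           distance=levenshtein(text, text_out))
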