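"""Character-stage normalization.

The character stage case-folds A-Z to a-z, collapses whitespace runs, and
applies per-character rules from the character rule bank.  Lowercase
letters, digits, and a small set of basic punctuation are pre-allowed and
never inventoried; every other character needs a curator decision before an
item containing it can pass validation.  An item touching a character under
an ``invalidate`` rule fails and is returned unmodified ("invalid, not
normalized"); an item left with an undecided character fails validation but
still receives all known rules.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

from .atoms import bracketed_spans, in_spans
from .metrics import levenshtein
from .rules import RuleStore

__all__ = [
    "CharStageResult",
    "preallowed_characters",
    "inventory_characters",
    "normalize_chars",
]

#: basic punctuation pre-allowed alongside a-z and 0-9
DEFAULT_PUNCTUATION = " -.,:()/"

_WS_RE = re.compile(r"\s+")


def preallowed_characters(punctuation: str = DEFAULT_PUNCTUATION) -> frozenset[str]:
    """Characters valid without any rule: a-z, 0-9, and basic punctuation."""
    letters = {chr(c) for c in range(ord("a"), ord("z") + 1)}
    digits = {chr(c) for c in range(ord("0"), ord("9") + 1)}
    return frozenset(letters | digits | set(punctuation))


@dataclass(frozen=True)
class CharStageResult:
    text_out: str
    valid: str  # pass | fail_invalidated | fail_unknown_unit
    distance: int


def collapse_whitespace(text: str) -> str:
    return _WS_RE.sub(" ", text).strip()


def _folded(text: str) -> str:
    """Whitespace-collapsed, case-folded text; bracketed atoms kept verbatim."""
    text = collapse_whitespace(text)
    spans = bracketed_spans(text)
    return "".join(c if in_spans(i, spans) else c.lower()
                   for i, c in enumerate(text))


def inventory_characters(items: Iterable[str], store: RuleStore,
                         punctuation: str = DEFAULT_PUNCTUATION,
                         context_cap: int = 5) -> RuleStore:
    """Record every distinct non-pre-allowed character into the review bank.

    Characters are counted after case folding and whitespace collapsing, so
    uppercase letters (handled by the built-in fold) never reach review.
    Characters inside bracketed atoms are exempt.
    """
    if store.level != "character":
        raise ValueError("inventory_characters requires a character-level store")
    allowed = preallowed_characters(punctuation)
    counts: dict[str, int] = {}
    contexts: dict[str, list[str]] = {}
    for item in items:
        folded = _folded(item)
        spans = bracketed_spans(folded)
        seen_here: set[str] = set()
        for i, c in enumerate(folded):
            if c in allowed or in_spans(i, spans):
                continue
            counts[c] = counts.get(c, 0) + 1
            if c not in seen_here and len(contexts.setdefault(c, [])) < context_cap:
                contexts[c].append(collapse_whitespace(item))
            seen_here.add(c)
    inventory = {c: (counts[c], contexts.get(c, [])) for c in counts}
    return store.record_new_units(inventory, context_cap=context_cap)


def normalize_chars(text: str, store: RuleStore,
                    punctuation: str = DEFAULT_PUNCTUATION) -> CharStageResult:
    """Apply the character bank to one item and validate the result.

    Order: the invalidate check runs first (so invalid items are returned
    untouched), then case folding, then replace/remove rules in one
    left-to-right pass.  Validation requires every remaining character
    outside bracketed atoms to be pre-allowed or under an ``allow`` rule.
    """
    if store.level != "character":
        raise ValueError("normalize_chars requires a character-level store")
    allowed = preallowed_characters(punctuation)
    folded = _folded(text)
    spans = bracketed_spans(folded)

    for i, c in enumerate(folded):
        if in_spans(i, spans):
            continue
        decision = store.decision_for(c)
        if decision is not None and decision.kind == "invalidate":
            return CharStageResult(text_out=text, valid="fail_invalidated", distance=0)

    out: list[str] = []
    for i, c in enumerate(folded):
        if in_spans(i, spans):
            out.append(c)
            continue
        decision = store.decision_for(c)
        if decision is None or decision.kind == "allow":
            out.append(c)
        elif decision.kind == "replace_with":
            out.append(decision.replacement or "")
        # remove: emit nothing
    text_out = "".join(out)

    valid = "pass"
    out_spans = bracketed_spans(text_out)
    for i, c in enumerate(text_out):
        if in_spans(i, out_spans):
            continue
        decision = store.decision_for(c)
        if c in allowed:
            continue
        if decision is not None and decision.kind == "allow":
            continue
        valid = "fail_unknown_unit"
        break

    return CharStageResult(text_out=text_out, valid=valid,
                           distance=levenshtein(text, text_out))
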