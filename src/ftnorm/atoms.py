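"""Protected atomic spans shared by all stages.

Two kinds of substrings are treated as indivisible atoms throughout the
pipeline: URLs (``scheme://...``) and bracketed reference spans such as
``[Fig F2]`` or ``[Table T1]``, the style used for in-document location
citations.  URLs are case-folded like ordinary text at the character stage
but receive no word rules; bracketed spans pass through every stage
verbatim and are never split internally.
"""

from __future__ import annotations

import re

URL_RE = re.compile(r"[A-Za-z][A-Za-z0-9+.-]*://\S+")
BRACKET_RE = re.compile(r"\[[^\[\]]*\]")
ATOM_RE = re.compile(f"{BRACKET_RE.pattern}|{URL_RE.pattern}")


def is_url(text: str) -> bool:
    return URL_RE.fullmatch(text) is not None


def is_bracketed(text: str) -> bool:
    return BRACKET_RE.fullmatch(text) is not None


def is_atom(text: str) -> bool:
    return is_url(text) or is_bracketed(text)


def bracketed_spans(text: str) -> list[tuple[int, int]]:
    """Half-open (start, end) spans of bracketed atoms in ``text``."""
    return [m.span() for m in BRACKET_RE.finditer(text)]


def protected_spans(text: str) -> list[tuple[int, int]]:
    """Spans that splitting and word rules must not reach into.

    Covers bracketed atoms, URLs, and parenthesized runs.
    """
    spans = [m.span() for m in ATOM_RE.finditer(text)]
    spans += [m.span() for m in re.finditer(r"\([^()]*\)", text)]
    return sorted(spans)


def in_spans(pos: int, spans: list[tuple[int, int]]) -> bool:
    return any(start <= pos < end for start, end in spans)
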