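"""List-item splitting: an accessory pre-phrase stage.

Free-text location fields often pack several distinct references into one
item ("[Table T1] and [Fig F1]").  Splitting such items into one segment
per reference lets each segment match a simple phrase pattern instead of
requiring a dedicated pattern per list permutation.  Segments keep both an
original-item identifier and a post-split index so they can be tracked
individually and traced back.

Split points are commas, semicolons, and the standalone conjunction "and";
URLs, bracketed reference spans, and parenthesized runs are never split
internally.  A *list-head distribution* heuristic expands elided heads:
in "supplementary figure 2, 3, 4" the bare numbers inherit the label
phrase of the preceding segment, yielding three full segments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

from .atoms import protected_spans, in_spans

__all__ = ["Segment", "split_segments", "attach_segment_metrics"]

_BOUNDARY_RE = re.compile(r"[,;]|\band\b")
_NUMBER_ONLY_RE = re.compile(r"\d+(?:\.\d+)?")
_HEADED_NUMBER_RE = re.compile(r"(.*[^\s\d].*?)\s+\d+(?:\.\d+)?$")
_STRIP_CHARS = " .,;"


@dataclass(frozen=True)
class Segment:
    """One location split out of a list-like item."""

    text: str
    original_index: Hashable
    split_index: int


def _raw_segments(text: str) -> list[str]:
    spans = protected_spans(text)
    cuts = [m for m in _BOUNDARY_RE.finditer(text)
            if not in_spans(m.start(), spans)]
    pieces: list[str] = []
    pos = 0
    for m in cuts:
        pieces.append(text[pos:m.start()])
        pos = m.end()
    pieces.append(text[pos:])
    stripped = [p.strip(_STRIP_CHARS) for p in pieces]
    return [p for p in stripped if p]


def _distribute_heads(pieces: list[str]) -> list[str]:
    out: list[str] = []
    for piece in pieces:
        if out and _NUMBER_ONLY_RE.fullmatch(piece):
            headed = _HEADED_NUMBER_RE.fullmatch(out[-1])
            if headed:
                out.append(f"{headed.group(1)} {piece}")
                continue
        out.append(piece)
    return out


def split_segments(text: str, original_index: Hashable = 0,
                   distribute_heads: bool = True) -> list[Segment]:
    """Split one word-valid item into segments.

    Non-list items yield a single segment whose text is the input (with
    terminal spaces/punctuation stripped).  With ``distribute_heads``, a
    bare-number segment following a segment that ends in a labelled number
    is expanded by copying that label phrase.
    """
    pieces = _raw_segments(text)
    if distribute_heads:
        pieces = _distribute_heads(pieces)
    if not pieces:
        stripped = text.strip(_STRIP_CHARS)
        pieces = [stripped] if stripped else []
    return [Segment(text=p, original_index=original_index, split_index=i)
            for i, p in enumerate(pieces)]


def attach_segment_metrics(
    segments: Sequence[Segment],
    validities: Mapping[tuple[Hashable, int], bool] | Sequence[bool],
) -> dict[Hashable, tuple[int, float]]:
    """Per-source (split_phrase_count, validity_rate) from segment verdicts.

    ``validities`` maps (original_index, split_index) to a pass/fail bool,
    or is a sequence parallel to ``segments``.  Both metrics are recorded
    once per source item, so distributions are not skewed by the row
    expansion splitting introduces; the result is invariant to segment
    order.
    """
    if not isinstance(validities, Mapping):
        validities = {(s.original_index, s.split_index): v
                      for s, v in zip(segments, validities, strict=True)}
    counts: dict[Hashable, int] = {}
    valid_counts: dict[Hashable, int] = {}
    for seg in segments:
        counts[seg.original_index] = counts.get(seg.original_index, 0) + 1
        if validities[(seg.original_index, seg.split_index)]:
            valid_counts[seg.original_index] = valid_counts.get(seg.original_index, 0) + 1
    return {src: (n, valid_counts.get(src, 0) / n) for src, n in counts.items()}
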