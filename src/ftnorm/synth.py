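"""Synthetic messy free-text corpora with known ground truth.

The generator emulates the kinds of variance seen in curated database
free-text fields: character variance (case, whitespace runs, en-dashes),
word variance (plural units, abbreviations, number words, filler words),
and phrase variance (reordered statistical phrases, worded ranges,
list-like concatenation of several locations).  Each item starts from a
canonical phrase drawn from the bundled phrase-type vocabulary and is
corrupted according to per-class rates, so normalization recovery is
directly measurable against the retained ground truth.

Every corruption the default rates apply is covered by the bundled rule
banks; a perfect rule bank therefore recovers essentially every item, and
the generator reports ambiguous collisions (two items whose corrupted
forms coincide while their truths differ) so a recovery shortfall can be
attributed.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field

__all__ = ["CorruptionSpec", "Corpus", "generate_corpus"]

_NUMBER_WORDS = {1: "one", 2: "two", 3: "three", 4: "four", 5: "five",
                 6: "six", 7: "seven", 8: "eight", 9: "nine", 10: "ten",
                 11: "eleven", 12: "twelve"}
_PLURALS = {"week": "weeks", "year": "years", "month": "months",
            "day": "days", "hour": "hours"}
_ABBREVS = {"week": ["wk", "wks"], "hour": ["h"]}
_UNITS = ("week", "year", "month", "day", "hour")
_STATS = ("mean", "median")
_PDB_IDS = ("1mfd", "1rzj", "1rzk")


@dataclass(frozen=True)
class CorruptionSpec:
    """Per-class corruption rates (all in [0, 1]) plus corpus shape.

    Identical spec + seed yields an identical corpus.
    """

    seed: int = 0
    n_items: int = 1000
    # character-level
    case_rate: float = 0.3
    whitespace_rate: float = 0.1
    endash_rate: float = 0.3
    # word-level
    plural_rate: float = 0.4
    abbrev_rate: float = 0.2
    numberword_rate: float = 0.1
    filler_rate: float = 0.2
    # phrase-level
    reorder_rate: float = 0.3
    list_rate: float = 0.3
    max_list_len: int = 4
    url_fraction: float = 0.2  # data_location only

    def __post_init__(self) -> None:
        for name in ("case_rate", "whitespace_rate", "endash_rate",
                     "plural_rate", "abbrev_rate", "numberword_rate",
                     "filler_rate", "reorder_rate", "list_rate",
                     "url_fraction"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")


@dataclass
class Corpus:
    items: list[str] = field(default_factory=list)
    truths: list[tuple[str, ...]] = field(default_factory=list)
    #: items whose corrupted form equals another item's despite different truths
    n_collisions: int = 0


def _number(rng: random.Random, allow_decimal: bool = True) -> str:
    if allow_decimal and rng.random() < 0.3:
        return f"{rng.randint(1, 80)}.{rng.randint(1, 9)}"
    return str(rng.randint(1, 80))


def _char_corrupt(text: str, spec: CorruptionSpec, rng: random.Random) -> str:
    if rng.random() < spec.endash_rate:
        text = text.replace("-", "–")
    if rng.random() < spec.case_rate:
        words = text.split(" ")
        i = rng.randrange(len(words))
        words[i] = words[i].capitalize() if rng.random() < 0.7 else words[i].upper()
        text = " ".join(words)
    if rng.random() < spec.whitespace_rate:
        spaces = [i for i, c in enumerate(text) if c == " "]
        if spaces:
            i = rng.choice(spaces)
            text = text[:i] + "  " + text[i + 1:]
    return text


def _corrupt_age(canonical: str, unit: str, n_values: list[str],
                 form: str, spec: CorruptionSpec, rng: random.Random) -> str:
    text = canonical
    # phrase-level rewording first, then word-level, then character-level
    if form == "statistical" and rng.random() < spec.reorder_rate:
        stat, rest = text.split(": ", 1)
        text = rng.choice([f"{stat} {rest}", f"{rest} {stat}", f"{stat} = {rest}"])
    elif form == "hyphenated range" and rng.random() < spec.reorder_rate:
        lo, rest = text.split("-", 1)
        hi, u = rest.split(" ", 1)
        text = rng.choice([f"{lo} to {hi} {u}", f"{lo} to {hi}-{u}"])
    if rng.random() < spec.plural_rate:
        text = text.replace(unit, _PLURALS[unit])
    elif unit in _ABBREVS and rng.random() < spec.abbrev_rate:
        text = text.replace(unit, rng.choice(_ABBREVS[unit]))
    if rng.random() < spec.numberword_rate:
        for value in n_values:
            if value.isdigit() and int(value) in _NUMBER_WORDS:
                text = text.replace(value, _NUMBER_WORDS[int(value)], 1)
                break
    last = text.split(" ")[-1]
    if (last.rstrip("s") in _UNITS or last in ("wk", "wks", "h")) \
            and rng.random() < spec.filler_rate:
        text = f"{text} old"
    return _char_corrupt(text, spec, rng)


def _age_canonical(spec: CorruptionSpec, rng: random.Random):
    form = rng.choice(["number unit", "hyphenated range", "statistical"])
    unit = rng.choice(_UNITS)
    if form == "number unit":
        n = _number(rng)
        return f"{n} {unit}", unit, [n], form
    if form == "hyphenated range":
        lo = rng.randint(1, 40)
        hi = lo + rng.randint(1, 40)
        return f"{lo}-{hi} {unit}", unit, [str(lo), str(hi)], form
    stat = rng.choice(_STATS)
    n = _number(rng)
    return f"{stat}: {n} {unit}", unit, [n], form


def _loc_canonical(spec: CorruptionSpec, rng: random.Random):
    """A canonical data-location segment and the word corruptions it allows."""
    kind = rng.choice(["bracket", "figure", "supplemental", "locnum", "pdb"])
    if kind == "bracket":
        ref = rng.choice(["Fig F", "Table T"]) + str(rng.randint(1, 9))
        return f"[{ref}]", kind
    if kind == "figure":
        return f"figure {rng.randint(1, 20)}", kind
    if kind == "supplemental":
        return f"supplemental figure {rng.randint(1, 20)}", kind
    if kind == "locnum":
        loc = rng.choice(["page", "data", "information", "file"])
        n = rng.randint(1, 12000)
        if loc == "file":
            return f"additional file {n % 20 + 1}", kind
        return f"{loc} {n}", kind
    return f"pdb {rng.choice(_PDB_IDS)}", kind


def _corrupt_loc_segment(canonical: str, kind: str, spec: CorruptionSpec,
                         rng: random.Random) -> str:
    text = canonical
    if kind == "figure" and rng.random() < spec.abbrev_rate:
        text = text.replace("figure", rng.choice(["fig.", "fig"]))
    elif kind == "supplemental" and rng.random() < spec.abbrev_rate:
        text = text.replace("supplemental figure",
                            rng.choice(["suppl fig.", "supplemental figs."]))
    if kind != "bracket" and rng.random() < spec.case_rate:
        words = text.split(" ")
        i = rng.randrange(len(words))
        words[i] = words[i].capitalize() if rng.random() < 0.7 else words[i].upper()
        text = " ".join(words)
    return text


def _url_item(spec: CorruptionSpec, rng: random.Random) -> tuple[str, str]:
    peptide = "".join(rng.choice(string.ascii_lowercase) for _ in range(9))
    truth = f"https://hla-ligand-atlas.org/peptide/{peptide}"
    item = truth
    if rng.random() < spec.case_rate:
        item = f"https://hla-ligand-atlas.org/peptide/{peptide.upper()}"
    return item, truth


def generate_corpus(spec: CorruptionSpec, template_set: str) -> Corpus:
    """Generate ``spec.n_items`` corrupted items with ground truth retained.

    ``template_set`` is ``"age"`` (single-phrase items, splitter off) or
    ``"data_location"`` (location segments, optionally list-like, splitter
    on).  With all rates zero the corpus is already canonical.
    """
    if template_set not in ("age", "data_location"):
        raise ValueError(f"unknown template set {template_set!r}")
    rng = random.Random(spec.seed)
    corpus = Corpus()
    for _ in range(spec.n_items):
        if template_set == "age":
            canonical, unit, n_values, form = _age_canonical(spec, rng)
            item = _corrupt_age(canonical, unit, n_values, form, spec, rng)
            corpus.items.append(item)
            corpus.truths.append((canonical,))
            continue
        if rng.random() < spec.url_fraction:
            item, truth = _url_item(spec, rng)
            corpus.items.append(item)
            corpus.truths.append((truth,))
            continue
        if rng.random() < spec.list_rate:
            k = rng.randint(2, max(2, spec.max_list_len))
            pairs = [_loc_canonical(spec, rng) for _ in range(k)]
            segments = [_corrupt_loc_segment(c, kind, spec, rng)
                        for c, kind in pairs]
            joiner = rng.choice([", ", ",", " and ", ", and "])
            corpus.items.append(joiner.join(segments))
            corpus.truths.append(tuple(c for c, _ in pairs))
        else:
            canonical, kind = _loc_canonical(spec, rng)
            corpus.items.append(_corrupt_loc_segment(canonical, kind, spec, rng))
            corpus.truths.append((canonical,))

    seen: dict[str, tuple[str, ...]] = {}
    for item, truth in zip(corpus.items, corpus.truths):
        if item in seen and seen[item] != truth:
            corpus.n_collisions += 1
        else:
            seen[item] = truth
    return corpus
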