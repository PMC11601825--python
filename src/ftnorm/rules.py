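"""Review/reference rule banks for character- and word-level normalization.

A rule bank is a pair of TSV files.  The *review* file is machine-generated:
one row per distinct text unit (a character or a word) found in the data,
with example contexts and an occurrence count, awaiting a curator's action
decision.  The curator decides by filling exactly one of four action columns
(``replace_with``, ``remove``, ``invalidate``, ``allow``); on the next run
decided rows are promoted into the *reference* file, the bank of rules that
actually drives normalization.  Word rows may additionally carry a
``category`` label used by the phrase stage.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "ActionDecision",
    "RuleRow",
    "RuleStore",
    "load_rulestore",
    "write_rulestore",
]

ACTION_KINDS = ("replace_with", "remove", "invalidate", "allow")

#: upper bound on example context strings kept per rule row
CONTEXT_CAP = 5
_CONTEXT_SEP = " | "


@dataclass(frozen=True)
class ActionDecision:
    """A curator's per-unit choice: replace, remove, invalidate, or allow."""

    kind: str
    replacement: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ACTION_KINDS:
            raise ValueError(f"unknown action kind: {self.kind!r}")
        if self.kind == "replace_with":
            if not self.replacement:
                raise ValueError("replace_with requires non-empty replacement text")
        elif self.replacement is not None:
            raise ValueError(f"{self.kind} does not take replacement text")


@dataclass
class RuleRow:
    """One text unit with its contexts, count, and optional decision/category."""

    unit: str
    contexts: list[str] = field(default_factory=list)
    count: int = 1
    decision: ActionDecision | None = None
    category: str | None = None

    def __post_init__(self) -> None:
        if not self.unit:
            raise ValueError("rule unit must be non-empty")
        if self.count < 0:
            raise ValueError("count must be non-negative")


class RuleStore:
    """The review + reference banks for one level ({'character', 'word'}).

    A unit appears in at most one of the two banks; lookup by unit is
    therefore unique.  Category labels are only meaningful at word level.
    """

    def __init__(self, level: str, rows: Iterable[RuleRow] = (),
                 reference_rows: Iterable[RuleRow] = ()) -> None:
        if level not in ("character", "word"):
            raise ValueError(f"level must be 'character' or 'word', got {level!r}")
        self.level = level
        self.review: dict[str, RuleRow] = {}
        self.reference: dict[str, RuleRow] = {}
        for row in rows:
            self._add(row, self.review)
        for row in reference_rows:
            if row.decision is None:
                raise ValueError(f"reference row {row.unit!r} has no action decision")
            self._add(row, self.reference)

    def _add(self, row: RuleRow, bank: dict[str, RuleRow]) -> None:
        if row.category is not None and self.level == "character":
            raise ValueError(f"category set on character row {row.unit!r}")
        if row.unit in self.review or row.unit in self.reference:
            raise ValueError(f"duplicate unit across rule banks: {row.unit!r}")
        bank[row.unit] = row

    # -- queries ---------------------------------------------------------

    def lookup(self, unit: str) -> RuleRow | None:
        """Return the row for ``unit`` from either bank, or None."""
        return self.reference.get(unit) or self.review.get(unit)

    def decision_for(self, unit: str) -> ActionDecision | None:
        """Return the *reference* decision for ``unit`` (review rows do not act)."""
        row = self.reference.get(unit)
        return row.decision if row is not None else None

    def category_for(self, unit: str) -> str | None:
        row = self.reference.get(unit)
        return row.category if row is not None else None

    def units(self) -> set[str]:
        return set(self.review) | set(self.reference)

    # -- evolution -------------------------------------------------------

    def promote_decided(self) -> "RuleStore":
        """Move review rows that carry an action decision into the reference bank.

        Pure reorganization: the union of units is unchanged, and the
        operation is idempotent.
        """
        decided = [u for u, r in self.review.items() if r.decision is not None]
        for unit in decided:
            self.reference[unit] = self.review.pop(unit)
        return self

    def record_new_units(
        self, inventory: Mapping[str, tuple[int, list[str]]],
        context_cap: int = CONTEXT_CAP,
    ) -> "RuleStore":
        """Fold an inventory ``unit -> (count, contexts)`` into the banks.

        Unknown units gain a review row; counts/contexts of known rows are
        refreshed in place.  Decisions and categories are never altered.
        """
        for unit, (count, contexts) in inventory.items():
            kept = list(contexts[:context_cap])
            row = self.lookup(unit)
            if row is None:
                self.review[unit] = RuleRow(unit=unit, contexts=kept, count=count)
            else:
                row.count = count
                row.contexts = kept
        return self

    def decide(self, unit: str, action: str, replacement: str | None = None,
               category: str | None = None, force: bool = False) -> None:
        """Record a decision for an inventoried unit (promote applies it)."""
        row = self.lookup(unit)
        if row is None:
            raise KeyError(f"unit {unit!r} is in neither review nor reference")
        if row.decision is not None and not force:
            raise ValueError(
                f"unit {unit!r} already has a decision ({row.decision.kind}); use force"
            )
        row.decision = ActionDecision(action, replacement)
        if category is not None:
            if self.level == "character":
                raise ValueError("categories apply to word rules only")
            row.category = category

    # -- equality (used by round-trip tests) -----------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RuleStore):
            return NotImplemented
        return (self.level == other.level
                and self.review == other.review
                and self.reference == other.reference)


# -- TSV input/output ----------------------------------------------------

_CHAR_COLUMNS = ["unit", "context", "count", "replace_with", "remove",
                 "invalidate", "allow"]
_WORD_COLUMNS = _CHAR_COLUMNS + ["category"]


def _columns(level: str) -> list[str]:
    return _WORD_COLUMNS if level == "word" else _CHAR_COLUMNS


def _parse_row(record: dict[str, str], level: str, path: Path, lineno: int) -> RuleRow:
    record = {k: (v or "") for k, v in record.items() if k is not None}
    unit = record.get("unit", "")
    if not unit:
        raise ValueError(f"{path}:{lineno}: empty unit")
    actions = [(k, record.get(k, "")) for k in ACTION_KINDS if record.get(k, "")]
    if len(actions) > 1:
        names = ", ".join(k for k, _ in actions)
        raise ValueError(
            f"{path}:{lineno}: conflicting action decisions ({names}) on unit {unit!r}"
        )
    decision = None
    if actions:
        kind, cell = actions[0]
        decision = ActionDecision(kind, cell if kind == "replace_with" else None)
    raw_count = record.get("count", "") or "0"
    try:
        count = int(raw_count)
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: bad count {raw_count!r}") from exc
    context = record.get("context", "")
    contexts = context.split(_CONTEXT_SEP) if context else []
    category = record.get("category") or None
    if level == "character":
        category = None
    return RuleRow(unit=unit, contexts=contexts, count=count,
                   decision=decision, category=category)


def _read_bank(path: Path | None, level: str) -> list[RuleRow]:
    if path is None or not Path(path).exists():
        return []
    rows: list[RuleRow] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t", quoting=csv.QUOTE_NONE)
        for lineno, record in enumerate(reader, start=2):
            rows.append(_parse_row(record, level, Path(path), lineno))
    return rows


def load_rulestore(review_path: str | Path | None,
                   reference_path: str | Path | None,
                   level: str) -> RuleStore:
    """Load a rule bank pair; an absent file is an empty bank.

    Review rows may carry decisions (entered by the curator, not yet
    promoted); reference rows must.  A unit present in both files is a hard
    error naming the unit, as are rows with two action decisions.
    """
    review = _read_bank(Path(review_path) if review_path else None, level)
    reference = _read_bank(Path(reference_path) if reference_path else None, level)
    store = RuleStore(level)
    for row in reference:
        if row.decision is None:
            raise ValueError(f"reference row {row.unit!r} has no action decision")
        store._add(row, store.reference)
    for row in review:
        store._add(row, store.review)
    return store


def _format_row(row: RuleRow, level: str) -> dict[str, str]:
    record = {c: "" for c in _columns(level)}
    record["unit"] = row.unit
    record["context"] = _CONTEXT_SEP.join(row.contexts)
    record["count"] = str(row.count)
    if row.decision is not None:
        if row.decision.kind == "replace_with":
            record["replace_with"] = row.decision.replacement or ""
        else:
            record[row.decision.kind] = "x"
    if level == "word" and row.category:
        record["category"] = row.category
    return record


def _write_bank(rows: Iterable[RuleRow], path: Path, level: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_columns(level), delimiter="\t",
                                quoting=csv.QUOTE_NONE, quotechar=None,
                                lineterminator="\n")
        writer.writeheader()
        for row in sorted(rows, key=lambda r: r.unit):
            writer.writerow(_format_row(row, level))


def write_rulestore(store: RuleStore, review_path: str | Path,
                    reference_path: str | Path) -> None:
    """Write both banks as unquoted UTF-8 TSV; load(write(store)) == store."""
    _write_bank(store.review.values(), Path(review_path), store.level)
    _write_bank(store.reference.values(), Path(reference_path), store.level)
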