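"""End-to-end orchestration: config, staged runs, and the review loop.

The pipeline applies the cascade char → word → (split) → phrase.  Each
stage first promotes decided review rows into the reference bank, then
inventories unseen units into review (so the curator sees what still needs
a decision), then normalizes and validates.  An item failing a stage is
never presented to later stages.

Two surfaces are provided: :func:`normalize_item` runs the whole cascade on
one string in memory (used heavily by tests and the synthetic-recovery
check), and :func:`run_stage` is the file-based workflow behind the CLI,
reading/writing TSVs so a curator can iterate on rule files between runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import chars, phrases, splitting, words
from .metrics import StageReport, build_stage_report, export_summary
from .phrases import PhraseType, load_phrase_types, write_phrase_types
from .rules import RuleStore, load_rulestore, write_rulestore

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StagedItem", "normalize_item", "run_stage",
           "run_all", "decide"]

STAGES = ("char", "word", "split", "phrase", "report")


@dataclass
class PipelineConfig:
    """Paths and knobs for one dataset's normalization run."""

    dataset: str
    input_path: str
    workdir: str = "."
    output_dir: str = "output"
    char_review: str | None = None
    char_reference: str | None = None
    word_review: str | None = None
    word_reference: str | None = None
    phrase_types: str | None = None
    splitter_enabled: bool = False
    context_cap: int = 5
    punctuation: str = chars.DEFAULT_PUNCTUATION
    seed: int = 0

    def __post_init__(self) -> None:
        defaults = {
            "char_review": f"{self.dataset}_char_review.tsv",
            "char_reference": f"{self.dataset}_char_reference.tsv",
            "word_review": f"{self.dataset}_word_review.tsv",
            "word_reference": f"{self.dataset}_word_reference.tsv",
            "phrase_types": f"{self.dataset}_phrase_types.tsv",
        }
        for name, default in defaults.items():
            if getattr(self, name) is None:
                setattr(self, name, default)

    def path(self, name: str) -> Path:
        return Path(self.workdir) / getattr(self, name)

    def out(self, filename: str) -> Path:
        return Path(self.workdir) / self.output_dir / filename

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        if cfg.workdir == ".":
            cfg.workdir = str(Path(path).parent)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True, allow_unicode=True)


@dataclass
class StagedItem:
    """One input item's outputs, verdicts, and scores across the cascade.

    ``None`` verdicts mean the stage never saw the item (upstream failure).
    For split datasets the phrase fields describe the item's segments.
    """

    id: int
    raw: str
    character_text: str | None = None
    character_valid: str | None = None
    character_distance: int | None = None
    word_text: str | None = None
    word_valid: str | None = None
    word_distance: int | None = None
    segments: list[str] = field(default_factory=list)
    phrase_texts: list[str] = field(default_factory=list)
    phrase_verdicts: list[str] = field(default_factory=list)
    categorizations: list[str] = field(default_factory=list)
    matched_patterns: list[str | None] = field(default_factory=list)
    split_phrase_count: int | None = None
    validity_rate: float | None = None

    @property
    def phrase_valid(self) -> str | None:
        """Item-level phrase verdict: pass iff every segment passed."""
        if not self.phrase_verdicts:
            return None
        if all(v == "pass" for v in self.phrase_verdicts):
            return "pass"
        fails = [v for v in self.phrase_verdicts if v != "pass"]
        return fails[0]

    @property
    def phrase_distance(self) -> None:
        return None  # edit distance is not a sensible phrase-stage measure


def normalize_item(raw: str, char_store: RuleStore, word_store: RuleStore,
                   ruleset: Sequence[PhraseType], item_id: int = 0,
                   split: bool = False,
                   punctuation: str = chars.DEFAULT_PUNCTUATION) -> StagedItem:
    """Run one string through the full cascade with in-memory rule banks."""
    item = StagedItem(id=item_id, raw=raw)
    cres = chars.normalize_chars(raw, char_store, punctuation)
    item.character_text = cres.text_out
    item.character_valid = cres.valid
    item.character_distance = cres.distance
    if cres.valid != "pass":
        return item

    wres = words.normalize_words(cres.text_out, word_store)
    item.word_text = wres.text_out
    item.word_valid = wres.valid
    item.word_distance = wres.distance
    if wres.valid != "pass":
        return item

    if split:
        segs = splitting.split_segments(wres.text_out, original_index=item_id)
        item.segments = [s.text for s in segs]
    else:
        item.segments = [wres.text_out]
    for seg_text in item.segments:
        pres = phrases.normalize_phrase(seg_text, word_store, ruleset)
        item.phrase_texts.append(pres.text_out)
        item.phrase_verdicts.append(pres.valid)
        item.categorizations.append(pres.categorization)
        item.matched_patterns.append(pres.matched_pattern)
    item.split_phrase_count = len(item.segments)
    n = len(item.segments)
    item.validity_rate = (
        sum(v == "pass" for v in item.phrase_verdicts) / n if n else 0.0
    )
    return item


# -- file-based workflow -------------------------------------------------

def _read_items(path: Path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)


def _read_tsv(path: Path, stage_needed: str) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found: run the '{stage_needed}' stage first")
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _load_promote_inventory(config: PipelineConfig, level: str,
                            items: list[str]) -> RuleStore:
    short = "char" if level == "character" else "word"
    store = load_rulestore(config.path(f"{short}_review"),
                           config.path(f"{short}_reference"), level)
    store.promote_decided()
    before = set(store.review)
    if level == "character":
        chars.inventory_characters(items, store, config.punctuation,
                                   config.context_cap)
    else:
        words.inventory_words(items, store, config.context_cap)
    new_units = set(store.review) - before
    if new_units:
        logger.info("%s stage: %d new unit(s) added to review (%s)",
                    short, len(new_units), config.path(f"{short}_review"))
    write_rulestore(store, config.path(f"{short}_review"),
                    config.path(f"{short}_reference"))
    return store


def run_stage(config: PipelineConfig, stage: str) -> dict:
    """Run one stage of the file-based workflow; returns summary counts."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    if stage == "char":
        items = _read_items(Path(config.workdir) / config.input_path)
        store = _load_promote_inventory(config, "character", items)
        rows = []
        for i, raw in enumerate(items):
            res = chars.normalize_chars(raw, store, config.punctuation)
            rows.append({"id": i, "original": raw, "char_normalized": res.text_out,
                         "char_valid": res.valid, "char_distance": res.distance})
        frame = pd.DataFrame(rows)
        _write_tsv(frame, config.out("char.tsv"))
        n_pass = sum(r["char_valid"] == "pass" for r in rows)
        return {"stage": "char", "n": len(rows), "n_pass": n_pass,
                "n_review": len(store.review)}

    if stage == "word":
        char_out = _read_tsv(config.out("char.tsv"), "char")
        passing = char_out[char_out["char_valid"] == "pass"]
        texts = list(passing["char_normalized"])
        store = _load_promote_inventory(config, "word", texts)
        rows = []
        for item_id, text in zip(passing["id"], texts):
            res = words.normalize_words(text, store)
            rows.append({"id": item_id, "char_normalized": text,
                         "word_normalized": res.text_out,
                         "word_valid": res.valid, "word_distance": res.distance})
        _write_tsv(pd.DataFrame(rows), config.out("word.tsv"))
        n_pass = sum(r["word_valid"] == "pass" for r in rows)
        return {"stage": "word", "n": len(rows), "n_pass": n_pass,
                "n_review": len(store.review)}

    if stage == "split":
        word_out = _read_tsv(config.out("word.tsv"), "word")
        passing = word_out[word_out["word_valid"] == "pass"]
        rows = []
        for item_id, text in zip(passing["id"], passing["word_normalized"]):
            for seg in splitting.split_segments(text, original_index=item_id):
                rows.append({"segment_id": f"{item_id}.{seg.split_index}",
                             "original_id": item_id,
                             "split_index": seg.split_index,
                             "segment_text": seg.text})
        _write_tsv(pd.DataFrame(rows), config.out("split.tsv"))
        return {"stage": "split", "n_sources": len(passing), "n_segments": len(rows)}

    if stage == "phrase":
        store = load_rulestore(config.path("word_review"),
                               config.path("word_reference"), "word")
        pt_path = config.path("phrase_types")
        if not pt_path.exists():
            write_phrase_types([], pt_path)
            logger.info("generated blank phrase-type ruleset at %s", pt_path)
        ruleset = load_phrase_types(pt_path)
        if config.splitter_enabled:
            split_out = _read_tsv(config.out("split.tsv"), "split")
            units = [(r["original_id"], int(r["split_index"]), r["segment_text"])
                     for _, r in split_out.iterrows()]
        else:
            word_out = _read_tsv(config.out("word.tsv"), "word")
            passing = word_out[word_out["word_valid"] == "pass"]
            units = [(r["id"], 0, r["word_normalized"])
                     for _, r in passing.iterrows()]
        results = {}
        for original_id, split_index, text in units:
            results[(original_id, split_index)] = (
                text, phrases.normalize_phrase(text, store, ruleset))
        counts: dict[str, int] = {}
        passes: dict[str, int] = {}
        for (original_id, _), (_, res) in results.items():
            counts[original_id] = counts.get(original_id, 0) + 1
            passes[original_id] = passes.get(original_id, 0) + (res.valid == "pass")
        rows = []
        for (original_id, split_index), (text, res) in results.items():
            row = {"id": original_id, "split_index": split_index,
                   "word_normalized": text,
                   "categorization": res.categorization,
                   "matched_pattern": res.matched_pattern or "",
                   "phrase_normalized": res.text_out,
                   "phrase_valid": res.valid,
                   # per-source metrics recorded once, on the first segment
                   "split_phrase_count": "", "validity_rate": ""}
            if split_index == 0:
                row["split_phrase_count"] = counts[original_id]
                row["validity_rate"] = f"{passes[original_id] / counts[original_id]:.4f}"
            rows.append(row)
        _write_tsv(pd.DataFrame(rows), config.out("phrase.tsv"))
        n_pass = sum(res.valid == "pass" for _, res in results.values())
        return {"stage": "phrase", "n": len(results), "n_pass": n_pass}

    # report
    return _run_report(config)


def _run_report(config: PipelineConfig) -> dict:
    char_out = _read_tsv(config.out("char.tsv"), "char")
    items: dict[str, StagedItem] = {}
    for _, r in char_out.iterrows():
        items[r["id"]] = StagedItem(
            id=int(r["id"]), raw=r["original"],
            character_text=r["char_normalized"], character_valid=r["char_valid"],
            character_distance=int(r["char_distance"]))
    word_path = config.out("word.tsv")
    if word_path.exists():
        for _, r in pd.read_csv(word_path, sep="\t", dtype=str,
                                keep_default_na=False).iterrows():
            item = items[r["id"]]
            item.word_text = r["word_normalized"]
            item.word_valid = r["word_valid"]
            item.word_distance = int(r["word_distance"])
    phrase_path = config.out("phrase.tsv")
    if phrase_path.exists():
        for _, r in pd.read_csv(phrase_path, sep="\t", dtype=str,
                                keep_default_na=False).iterrows():
            item = items[r["id"]]
            item.phrase_texts.append(r["phrase_normalized"])
            item.phrase_verdicts.append(r["phrase_valid"])
    reports = [build_stage_report(items.values(), s)
               for s in ("character", "word", "phrase")]
    export_summary(reports, config.out("summary.tsv"),
                   plot_dir=config.out("plots"))
    return {"stage": "report", "summary": str(config.out("summary.tsv"))}


def run_all(config: PipelineConfig) -> list[dict]:
    """Run the full cascade (split only when enabled) plus the report."""
    order = ["char", "word"] + (["split"] if config.splitter_enabled else []) \
        + ["phrase", "report"]
    return [run_stage(config, s) for s in order]


def decide(config: PipelineConfig, level: str, unit: str, action: str,
           replacement: str | None = None, category: str | None = None,
           force: bool = False) -> None:
    """Record an action decision in the rule files (applied on next run)."""
    short = "char" if level == "character" else "word"
    store = load_rulestore(config.path(f"{short}_review"),
                           config.path(f"{short}_reference"), level)
    store.decide(unit, action, replacement, category, force)
    write_rulestore(store, config.path(f"{short}_review"),
                    config.path(f"{short}_reference"))
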