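# ftnorm

Staged, rule-based normalization of free-text database fields, built for
curation teams who need to remove *variance* — representations that differ
without differing in meaning — from fields like a subject-age column
("6–8 weeks", "6-8 wks", "6 to 8 weeks") or a publication data-location
column ("Fig. 6", "figure 6", "[Fig F2],[Fig F2], Fig. 6.") so the values
become searchable and mappable to ontology terms.

Automatic spell-checkers over- or under-correct on this kind of data, so
ftnorm is deliberately user-in-the-loop: the tool inventories what it finds,
and a curator decides what each unit means. Normalization proceeds in three
validated stages, each driven by rules a curator authors in plain TSV files:

1. **Character stage** — case-folds A–Z, collapses whitespace, and applies
   per-character rules. Lowercase letters, digits, and basic punctuation
   (space, `-`, `.`, `,`, `:`, `(`, `)`, `/`) are pre-allowed; every other
   character is inventoried into a *review* TSV with its contexts and
   occurrence count, awaiting one of four action decisions:
   `replace_with`, `remove`, `invalidate`, or `allow`. Decided rows are
   promoted into a *reference* TSV — the rule bank — on the next run.
   An item passes when only allowed characters remain.
2. **Word stage** — tokenizes character-valid items (delimiters: spaces,
   hyphens, and common punctuation; `6.3` stays one number token; URLs and
   bracketed references like `[Fig F2]` are atomic), inventories unknown
   words, and applies the same four decisions per word. Word rules may also
   assign a *category* (`unit`, `statistical`, `range_indicator`, ...)
   consumed by the phrase stage.
3. **Phrase stage** — renders each word-valid item as a categorization
   string, e.g. `6 week mean` → `[number(0)][unit(1)][statistical(2)]`,
   matches it against a named pattern ruleset, and rewrites matches through
   the pattern's standard-form template (`[2]: [0] [1]` → `mean: 6 week`).
   Patterns are flagged valid or invalid — a bare number is a meaningless
   age, so `[number(0)]` can be declared an *invalid* pattern — and items
   pass only by matching a valid pattern.

An accessory **splitter** runs before the phrase stage for list-like fields,
dividing `[Table T1] and [Fig F1]` into per-location segments with
original/post-split indices, a *split phrase count*, and a per-source
*validity rate* (valid segments / split phrase count, recorded once per
input item). Character- and word-stage changes are scored with Levenshtein
edit distances; phrase-stage rewrites reorder words, so distance is not
tracked there.

## Worked example

Normalize four messy age values with the bundled age rule bank:

```bash
printf 'Six week old\nMedian age 6.3 years\n20–67 yrs\n8-10\n' > items.txt
python -c "from ftnorm import PipelineConfig; \
  PipelineConfig(dataset='age', input_path='items.txt').to_yaml('config.yaml')"
# copy the bundled age_*.tsv reference/phrase files into the working dir, then:
ftnorm all --config config.yaml
```

```
INFO word stage: 1 new unit(s) added to review (age_word_review.tsv)
stage=char   n=4  n_pass=4  n_review=0
stage=word   n=4  n_pass=3  n_review=1
stage=phrase n=3  n_pass=2
```

`Six week old` became `6 week` (case fold; `six`→`6`; `old` removed) and
`Median age 6.3 years` became `median: 6.3 year` via the `statistical`
pattern. `8-10` matched the pattern `range without unit`, which is flagged
invalid — a unitless range is not a usable age — so it fails phrase
validation unchanged. `20–67 yrs` failed word validation because `yrs` has
no rule yet; it now sits in `age_word_review.tsv` with its context and
count. Decide it and rerun:

```bash
ftnorm decide --config config.yaml --level word --unit yrs \
       --action replace_with --replacement year
ftnorm all --config config.yaml
```

```
stage=word   n=4  n_pass=4  n_review=0
```

and the item's word stage row is now `20-67 yrs → 20-67 year` (pass,
distance 3). `output/summary.tsv` tabulates per-stage counts, validity
rates, and distance histograms; `output/plots/` holds the histogram PNGs.

The library surface mirrors the CLI: `normalize_chars`, `normalize_words`,
`normalize_phrase`, `split_segments`, and `normalize_item` run the cascade
in memory, and `ftnorm.synth.generate_corpus` produces seeded messy corpora
with ground truth for benchmarking recovery.

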