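# Methods

## The normalization model

ftnorm treats a free-text field as a population of short strings whose
meaning-preserving variability occurs at three levels, and it removes that
variability with three ordered, individually validated stages. The design
premise is that rule *application* should be fully automatic and
reproducible while rule *authorship* stays with a human curator: the tool
never guesses a correction, it only inventories what it cannot yet handle
and waits for a decision.

**Review/reference workflow.** At the character and word levels every
distinct unit that is not intrinsically allowed is recorded in a review TSV
(unit, up to 5 example contexts, occurrence count, four empty action
columns). A curator fills exactly one action column per row —
`replace_with` (with the replacement text), `remove`, `invalidate`, or
`allow` — and on the next run decided rows are promoted to the reference
TSV, the bank actually applied. Promotion is a pure reorganization
(idempotent, unit-conserving), and a unit can live in only one bank, so
lookup is unique and there is no rule precedence to reason about. Rows with
two filled action columns are rejected at load rather than prioritized;
failing loudly protects the rule bank's integrity. Counts and contexts of
already-known units (in either bank) are refreshed on reruns; decisions
never are.

**Character stage.** The invalidate check runs before any modification, so
an invalidated item is returned byte-identical ("invalid, not
normalized"). Otherwise whitespace runs collapse to single spaces, A–Z
folds to a–z, and replace/remove rules apply in one left-to-right pass.
Case folding is a built-in transform rather than 26 replace rules: the
worked examples show wholesale lowercasing (including a URL path scored at
edit distance 9) with no per-letter rules. The pre-allowed set is lowercase
letters, digits, and the basic punctuation ` -.,:()/` — the minimal set
covering every passing worked example; it is a parameter
(`punctuation` in `PipelineConfig`) because different fields legitimately
differ here (note `=` is *not* pre-allowed; the age bank allows it
explicitly). Items left with an undecided character fail validation but
still receive all known rules, so a curator sees the most-normalized
version in review contexts.

**Word stage.** Words are maximal runs between delimiter characters
(` -,.:;()/=`), with two lexical exceptions chosen to match how these
fields are actually written: a decimal point flanked by digits stays inside
its number token (`6.3` must categorize as one number), and protected
atoms are single tokens. Numeric tokens are intrinsically allowed and
auto-categorized `number` — enumerating numerals as rules would be
unbounded — and for the same reason they are not inventoried. Removal
keeps the removed token's leading delimiter run and drops the trailing
one, then collapses doubled spaces, which yields `6-10 week` from
`6-10 week old`. Replacement substitutes whole tokens only (a `wk` rule
must not corrupt a hypothetical `wkend`), and a token produced by a
replace rule is accepted as normalized even if the replacement text has no
allow row of its own.

**Protected atoms.** URLs (`scheme://...`) and bracketed reference spans
(`[...]`, the citation style used for in-document figure/table pointers in
the source material this package was validated against) are atomic
throughout: one token, exempt from word rules, never split internally.
Bracketed spans additionally skip character-stage case folding and
validation — they are treated as opaque identifiers — and carry the
intrinsic category `bracketed_ref` (URLs: `url`) so a one-line phrase
pattern can validate them. URLs *are* case-folded, which is the published
behavior for HLA Ligand Atlas peptide paths and is what produces the
distance-9 spike for 9-letter uppercase paths.

**Phrase stage.** Categorization maps each token to the category column of
its word reference row, defaulting to `unknown`. Matching is exact
full-sequence equality of category labels against the phrase-type ruleset,
first-in-file-order on (warned) duplicate patterns; no wildcards or
repetition operators, because list-like repetition is handled upstream by
the splitter — that is why the two mechanisms are paired. Delimiters
between tokens deliberately do not participate in matching (`mean 29.8
year`, `mean: 29.8 year`, and `median : 7.5 year` are one pattern); the
standard-form template re-specifies all spacing and punctuation, which is
also what makes phrase normalization idempotent for rulesets whose
standard forms match their own patterns (asserted in tests for the bundled
rulesets). Items matching an invalid pattern or nothing keep their
word-normalized text, mirroring the invalidate convention. The two failure
modes (`fail_invalid_pattern` vs `fail_no_match`) are counted separately
because they call for different curator actions: authoring a new pattern
vs accepting that a structure is inherently unusable.

**Splitter.** An accessory pre-phrase stage, enabled per dataset
(`splitter_enabled`), for fields where one row packs several values.
Boundaries are commas, semicolons, and the standalone token `and`
(covering `, and`); segments are stripped of flanking spaces and `.,;`.
The *list-head distribution* heuristic copies an elided label phrase onto
bare trailing numbers (`supplementary figure 2, 3` → two full segments);
it fires only when the preceding expanded segment ends in a number
preceded by non-numeric text, and can be disabled. Numeric ranges such as
`figures 2-5` are kept as one segment — expanding them would manufacture
data the string does not contain. Split phrase count and validity rate are
recorded once per source item so their distributions are not inflated by
the row expansion.

**Distance scoring.** Levenshtein distances (unit cost, unicode
codepoints, via `edlib`) are logged at the character stage (original vs
character-normalized) and word stage (character-normalized vs
word-normalized). A word-stage score of 1 typically marks a
plural-to-singular unit rule. No distance is computed at the phrase stage:
template rewriting reorders words, so edit distance stops measuring
meaning-preserving continuity there.

## Bundled rule banks

`ftnorm/data/` ships reference banks and phrase-type rulesets for the two
field types the package was developed against: `age` (21 word-rule rows, 9
phrase patterns, splitter off) and `data_location` (splitter on). They
reproduce every published worked example and are the fixtures for the test
suite and the synthetic-recovery benchmark; they make no claim to cover
either field exhaustively. One published sample-items table is internally
inconsistent (a `fig → figure` rule listed as applied is absent from one
row's word-normalized column while the same row's split output shows it
applied); ftnorm applies rules uniformly and follows the split output.

## The synthetic generator

`ftnorm.synth.generate_corpus` draws canonical phrases from the bundled
vocabulary (age: number-unit, hyphenated range, statistical; location:
bracketed references, figure/page/data numbers, PDB identifiers,
HLA-Ligand-Atlas-style URLs) and corrupts them with the variance classes
the pipeline targets: case, doubled whitespace, en-dashes (character);
plural units, abbreviations, number words, filler words (word); reordered
statistical phrases, worded ranges, list concatenation (phrase). Default
rates (e.g. 30% case, 40% plural, 30% list-likeness, 20% URL fraction)
are set so a typical corpus exercises every rule class at once while most
items carry more than one corruption. Every corruption the defaults can
emit is covered by the bundled banks, so recovery failures indicate
pipeline defects, not vocabulary gaps; the generator also reports
*collisions* (identical corrupted forms with different truths) so any
shortfall can be attributed. What the generator does not emulate: genuinely
novel vocabulary, misspellings beyond the fixed abbreviation list, nested
or ragged lists, and the heavy-tailed frequency skew of real fields —
passing the recovery benchmark therefore demonstrates mechanical
correctness of the cascade, not field-completeness of any rule bank.

## Numerical and reporting choices

- Stage validity rates use items actually processed at that stage as the
  denominator (upstream failures are "skipped", not failed); a
  whole-dataset denominator (`validity_rate_all`) is emitted alongside,
  since failure shares are sometimes quoted against all items.
- Degenerate inputs: an empty string tokenizes to no tokens, passes the
  character stage at distance 0, and yields an empty category sequence; an
  all-delimiter string splits to zero segments and is reported as one
  stripped segment if non-empty.
- All TSV I/O is UTF-8, tab-separated, unquoted (a quoting dialect would
  be ambiguous for free text containing commas); round-trips are asserted
  lossless field-for-field.
- Outputs are byte-deterministic given identical inputs and rule files;
  the generator is deterministic under a fixed seed.
- Test and benchmark problem sizes: the oracle cross-check uses 1,000
  random string pairs (lengths ≤ 30); the recovery benchmark uses 5,000
  items (2,500 per field type, seed 42) with a ≥ 99% recovery bar.

## Known limitations

- Multi-word replacement texts are applied verbatim but only the whole
  replacement string is tracked for validity, so a replacement containing
  a delimiter should itself be covered by allow rules.
- The head-distribution heuristic cannot recover heads elided *forward*
  ("2, 3 and 4 weeks" distributes nothing at the splitter; the age
  pipeline leaves such lists to phrase patterns).
- Exact-sequence phrase matching means every structural variant needs its
  own pattern row; this is a deliberate precision-over-recall trade, and
  categorization-string frequencies in the phrase output are the intended
  guide for choosing which patterns to author next.
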