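# Methods

## Model and procedure

`sheetmerge` treats column matching as set similarity in a semantic space.

1. **Term sets.** Each column yields the set of lowercase unigrams from its
   header and (for discrete columns) its values. The tokenizer splits on any
   run of non-alphanumeric characters, drops pure-number tokens, and keeps
   mixed alphanumerics. Keeping tokens like `a1` is deliberate: columns that
   encode unrelated phenotypes with letter–number categories can then look
   alike, a liberal-merging bias the evaluation module must be able to
   exhibit rather than silently avoid.
2. **Abbreviation pre-expansion (optional).** A two-column CSV maps
   abbreviations to expansion phrases; matched terms gain the expansion's
   unigrams while the original token is retained (retention can only add
   matching signal). Applied once, never recursively. A general-purpose
   medical dictionary can *hurt* specialised data — e.g. resolving `pr` to
   "prothrombin ratio" when a breast-tumor table means "progesterone
   receptor" — which is why the dictionary is pluggable and off by default.
3. **Collocate expansion.** Each term's collocates are read from a TSV
   lexicon (`term<TAB>comma-separated collocates`) and unioned into the
   term set. Expansion is one level deep and membership is binary; no
   frequency weighting (deliberately: the contract is presence/absence).
   The lexicon is file-backed so any corpus — a licensed concordancer
   export, WordNet relations, or a hand-written list — can supply it.
4. **Similarity.** Ochiai coefficient |A∩B|/√(|A||B|), identically the
   cosine of the 0/1 indicator vectors. Empty sets score 0 (avoids 0/0 and
   keeps blank columns unmergeable). Scores for each spreadsheet pair form a
   dense matrix; sizes here are at most a few hundred columns per sheet.
5. **Greedy selection.** Repeatedly take the globally maximal matrix cell,
   record the pair, delete its row and column. Ties break to the smallest
   row then column index — the tie-break is declared, not derived; some
   deterministic rule is required for reproducible runs. Selection ignores
   the threshold so diagnostics retain near-misses; pairs are merely
   *flagged* above/below. A pair scoring exactly at the threshold is
   accepted.
6. **Transitive grouping.** Merge groups are the connected components over
   all above-threshold pairs from every sheet pair. This implements the
   transitivity rule with no special casing: a below-threshold pair merges
   exactly when its columns are already connected through another sheet,
   and unpaired columns come out as singletons. Component structure is
   independent of the order sheet pairs are processed in. Columns of the
   same sheet are never compared, so a component can hold several columns
   of one sheet only through shared partners elsewhere.
7. **Labeling and export.** Group label = shortest member header (ties:
   lexicographically smallest); a user-edited plan overrides labels and
   membership wholesale. The merged CSV has one column per group, every
   input row exactly once, values byte-identical, empty cells where a
   row's sheet lacks the group, plus a `__source` provenance column.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `threshold` | 0.5 | minimum Ochiai score for a greedy pair to create an edge; the sweep utility exists to examine alternatives |
| abbreviation dict | none | optional CSV, see above |
| lexicon | required | TSV term→collocates; no query parameters (window, association measure, list length) are modeled — the file is taken as given |

Datatype inference: a column is *continuous* iff ≥ 90% of its non-empty
cells parse as finite numbers **and** it has more unique values than
max(10, half the non-empty count); otherwise *discrete*. Continuous columns
contribute header terms only — raw measurements are unit-bearing numbers,
not vocabulary, and unit-aware merging of continuous data is out of scope.
Low-cardinality numeric codes (0/1 flags) stay discrete, though their
pure-number values are then dropped by the tokenizer anyway.

## Scoring

Per-column accuracy against a hand-curated partition: a column is correct
iff its predicted group's member set equals its true group's (singleton in
both counts). Errors split exhaustively into: **ungrouped** (singleton in
the plan, grouped in truth), **overgrouped** (grouped in the plan, singleton
in truth), **misgrouped** (grouped in both, different groups); the counts
always sum to the column total. Exact-equality of member sets is the
strictest well-defined reading of per-column correctness; no partial credit
is given, and group labels are ignored (grouping, not naming, is scored).
`exclude_exact_matches` removes every column whose lowercased header occurs
in more than one sheet, isolating performance on columns only semantics can
match. The denominator counts physical columns, each once.

## Synthetic fixtures

The generator emulates a corpus of annotation spreadsheets with known truth:

* `n_groups` true groups each span `group_span` of the `n_sheets` sheets
  under distinct single-word headers (optionally duplicated exactly with
  probability `exact_duplicate_fraction`, to exercise the exact-match
  filter); members share a 4-word value vocabulary sampled into `n_rows`
  rows.
* Every term gets a `collocates_per_term`-long lexicon entry (default 10,
  the scale of published collocate lists). For group terms,
  `signature_overlap` of the list comes from the group's planted signature;
  within that share, `noise_overlap` is drawn instead from one global pool
  common to *all* columns. `noise_overlap` also sets the fraction of each
  group's value vocabulary drawn from a global ambiguous-value pool. Hence
  at `noise_overlap = signature_overlap` the cross-group collocate structure
  is indistinguishable from the within-group structure and accuracy must
  collapse; the constraint `noise_overlap ≤ signature_overlap` is enforced.
* `n_distractors` columns get private vocabulary and no signature.
* Vocabulary comes from a packaged word list (readable lexicons beat random
  strings when debugging); allocation is unique per run, with numbered
  fallbacks only under extreme configurations. Everything derives from one
  `random.Random(seed)`, so equal configs produce byte-identical files.

Defaults (4 sheets, 6 groups spanning 3, 8 distractors, signature 0.8,
noise 0.1, 8 rows) give within-group Ochiai around 0.85 and cross-group
around 0.1 — cleanly separable at the 0.5 operating point, which is what
the parameter-recovery tests assert. What the generator does **not**
emulate: multi-word and abbreviated headers, missing-data patterns,
continuous measurements with units, skewed value frequencies, and lexicon
gaps for domain jargon. Passing on fixtures therefore demonstrates the
machinery is correct under the stated separability model, not any
particular accuracy on real repository data.

## Numerical and degenerate-input choices

* Ochiai is computed on integer set sizes (`len(a & b) / sqrt(len(a)*len(b))`);
  agreement with the explicit bitwise-cosine computation is asserted to
  1e-12 in tests.
* Empty spreadsheet file: error. Header-only file: columns with zero rows.
  Ragged (short) rows are padded with empty strings and logged; overlong
  rows are an error. Blank headers become `column_<index>`; duplicate
  headers within a sheet are an error (columns are addressed by
  `(sheet_id, header)`).
* A fixture sheet that receives no columns under a degenerate configuration
  is dropped rather than emitted invalid.
* Find/replace matches whole cell values only — safer for categorical
  recoding than substring replacement.

## Problem sizes in the test suite

The greedy selector is verified against a full-rescan reference on every
binary 4×4 matrix (65,536 cases) and 500 random real matrices up to 8×8;
the similarity oracle on 1,000 random set pairs up to size 50; recovery and
conservation on 20 seeded corpora of ~26 columns across 4 sheets. These
sizes exercise every code path while keeping the default suite fast.

## Known limitations

Greedy selection is order-dependent by design and can differ from the
optimal assignment; the transitive-components rule inherits greedy's
liberal-merging bias (one bad edge fuses two groups). Single-level collocate
expansion cannot relate terms whose connection needs a two-hop chain. The
lexicon is static: out-of-vocabulary headers (institution codes,
abbreviations missing from the dictionary) expand to themselves only and
rarely merge. Continuous columns match on headers alone.
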