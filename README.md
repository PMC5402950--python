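# sheetmerge

Merge unstructured spreadsheets by collocate-expanded column similarity.

Synthesis studies — combining sample annotations from independently curated
datasets, whether tumor phenotype tables from public genomics repositories or
ecological monitoring records — stall on a tedious first step: the same
annotation appears under different column headers ("gender" here, "sex"
there) with no shared standard, so someone has to match columns by hand.
`sheetmerge` automates that step. It matches columns across CSV spreadsheets
using both their headers and their values, emits an editable merge plan, and
exports a single merged table without ever changing a cell value.

## The method

For column *x* of spreadsheet *k*, build the **term set** `l_xk`: the
lowercase unigrams of its header plus, for discrete columns, of all its
values (pure-number tokens are dropped). Expand it with every term's
**collocates** — words that co-occur with the term in a reference corpus,
supplied here as a plain TSV lexicon — giving the **expanded set** `c_xk`
with binary membership. Columns are compared with the Ochiai coefficient,

    s(x, y) = |c_xj ∩ c_yk| / sqrt(|c_xj| · |c_yk|),

which equals the cosine similarity of the sets' 0/1 indicator vectors. For
each pair of spreadsheets the coefficients form a matrix; a greedy pass
repeatedly takes the globally maximal cell and deletes its row and column,
pairing each column with at most one partner per sheet. Pairs scoring at or
above a threshold (default **0.5**) become edges, and connected components
over all accepted edges define the merge groups — so merging is transitive
across three or more sheets. Each group is labeled with its shortest member
header, and the merged CSV stacks every input row under the group labels,
with a `__source` provenance column.

An evaluation module scores a plan against a hand-curated grouping:
per-column accuracy plus a three-way error taxonomy (left ungrouped /
grouped when it should not be / placed in the wrong group), an exact-match
exclusion filter, and a threshold sweep. A seeded fixture generator builds
synthetic multi-sheet corpora with planted collocate signatures and a known
ground truth, so the whole pipeline is testable offline.

## Worked example

Sheet `A.csv` has one column (`gender`: male, female); sheet `B.csv` has two
(`sex`: male, female and `grade`: moderate, poor, well). The packaged
lexicon gives the gender/sex terms overlapping collocates. Materialize the
example and merge:

```sh
python -c "from sheetmerge.fixtures import worked_example_fixture, write_fixture; \
           write_fixture('.', *worked_example_fixture())"
sheetmerge -v merge A.csv B.csv --lexicon lexicon.tsv -o merged.csv --plan plan.json
```

which logs the one accepted pair and its similarity —

```
INFO sheetmerge.matching: accept ('A', 'gender') ~ ('B', 'sex') (score 0.960)
wrote plan.json and merged.csv (2 groups)
```

— and writes `merged.csv`:

```
sex,grade,__source
male,,A
female,,A
male,moderate,B
female,poor,B
,well,B
```

`gender` and `sex` share 24 of their 25 expanded-set members (Ochiai 0.96,
above the 0.5 threshold), so they merge under the shorter header `sex`;
`grade` shares nothing with the gender context and stays its own column.
A's rows have empty `grade` cells because sheet A never measured grade.
Edit `plan.json` to override any grouping and re-apply it with
`sheetmerge apply`. Scoring the plan against the packaged truth:

```sh
sheetmerge evaluate --plan plan.json --truth truth.json
```

```json
{
  "n_columns": 3,
  "n_correct": 3,
  "accuracy": 1.0,
  "errors_ungrouped": 0,
  "errors_overgrouped": 0,
  "errors_misgrouped": 0
}
```

All three columns are grouped exactly as the ground truth says.

## CLI

`sheetmerge merge | apply | evaluate | sweep | fixtures | replace` — see
`sheetmerge COMMAND --help`. `docs/methods.md` documents the model, its
parameters and the fixture generator in detail.
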