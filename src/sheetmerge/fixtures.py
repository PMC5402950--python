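"""Synthetic multi-spreadsheet fixtures with known ground truth.

Real inputs for this problem are sample-annotation spreadsheets from
independent studies: semantically equivalent columns carry different headers
but overlapping value vocabularies, and a reference corpus gives their terms
overlapping collocates.  The generator emulates exactly that structure with a
readable vocabulary drawn from a packaged word list:

* each *true group* spans ``group_span`` sheets under distinct synthetic
  headers, its columns sharing a value vocabulary and a planted collocate
  *signature*;
* *distractor* columns get private vocabulary and no signature;
* ``signature_overlap`` sets the fraction of each group term's collocate list
  drawn from the group signature, ``noise_overlap`` the fraction drawn from a
  single global pool shared by *every* column (and, symmetrically, the
  fraction of a group's value vocabulary drawn from a global ambiguous-value
  pool).  As noise_overlap rises toward signature_overlap, cross-group
  similarity approaches within-group similarity and merging must degrade.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator

from .io_csv import Column, Spreadsheet, save_plan, write_csv
from .lexicon import GENDER_COLLOCATES, CollocateLexicon, load_lexicon, save_lexicon
from .matching import MergeGroup, MergePlan, choose_label
from .termsets import classify_datatype

# Structural scale of one synthetic column, mirroring small annotation tables:
# a one-word header over a handful of categorical values.
_VALUES_PER_GROUP = 4
_VALUES_PER_DISTRACTOR = 3


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs for the generator; defaults give a cleanly separable corpus."""

    n_sheets: int = 4
    n_groups: int = 6
    group_span: int = 3
    n_distractors: int = 8
    collocates_per_term: int = 10
    signature_overlap: float = 0.8
    noise_overlap: float = 0.1
    n_rows: int = 8
    exact_duplicate_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("signature_overlap", "noise_overlap", "exact_duplicate_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_overlap > self.signature_overlap:
            raise ValueError("noise_overlap must not exceed signature_overlap")
        if self.n_sheets < 1 or self.n_rows < 1 or self.collocates_per_term < 1:
            raise ValueError("n_sheets, n_rows and collocates_per_term must be positive")
        if self.n_groups < 0 or self.n_distractors < 0:
            raise ValueError("n_groups and n_distractors must be non-negative")
        if self.n_groups > 0 and not 1 <= self.group_span <= self.n_sheets:
            raise ValueError(
                f"group_span must be in [1, n_sheets], got {self.group_span} "
                f"with n_sheets={self.n_sheets}"
            )


def load_wordlist() -> list[str]:
    text = resources.files("sheetmerge").joinpath("data/wordlist.txt").read_text("utf-8")
    seen: dict[str, None] = {}
    for w in text.split():
        seen.setdefault(w, None)
    return list(seen)


def _word_supply(rng: random.Random) -> Iterator[str]:
    """Unique readable words; falls back to numbered variants when the list
    runs dry (only under extreme configs)."""
    base = load_wordlist()
    shuffled = rng.sample(base, len(base))
    yield from shuffled
    suffix = 2
    while True:
        for w in shuffled:
            yield f"{w}{suffix}"
        suffix += 1


def _round(x: float) -> int:
    return int(x + 0.5)


def generate(
    config: FixtureConfig,
) -> tuple[list[Spreadsheet], CollocateLexicon, MergePlan]:
    """Build spreadsheets, a matching lexicon, and the true grouping."""
    rng = random.Random(config.seed)
    supply = _word_supply(rng)

    def draw(n: int) -> list[str]:
        return [next(supply) for _ in range(n)]

    cpt = config.collocates_per_term
    n_cross = _round(config.noise_overlap * cpt)
    n_within = _round(config.signature_overlap * cpt) - n_cross
    n_shared_values = _round(config.noise_overlap * _VALUES_PER_GROUP)

    global_pool = draw(cpt)  # collocates shared across *all* columns
    global_values = draw(_VALUES_PER_GROUP)  # ambiguous value words

    entries: dict[str, tuple[str, ...]] = {}

    def add_entry(term: str, signature: list[str] | None) -> None:
        if term in entries:
            return
        collocates = []
        if signature is not None:
            collocates += rng.sample(signature, n_within)
        collocates += rng.sample(global_pool, n_cross)
        collocates += draw(cpt - len(collocates))
        entries[term] = tuple(collocates)

    for word in global_values:
        add_entry(word, signature=None)

    # (header, value vocabulary) specs per sheet, then truth membership.
    specs: list[list[tuple[str, list[str]]]] = [[] for _ in range(config.n_sheets)]
    truth_groups: list[set[tuple[str, str]]] = []
    sheet_ids = [f"s{i + 1}" for i in range(config.n_sheets)]

    for _ in range(config.n_groups):
        member_sheets = sorted(rng.sample(range(config.n_sheets), config.group_span))
        signature = draw(cpt)
        own_values = draw(_VALUES_PER_GROUP - n_shared_values)
        shared_values = rng.sample(global_values, n_shared_values)
        vocab = own_values + shared_values
        first_header = draw(1)[0]
        members: set[tuple[str, str]] = set()
        for pos, sheet_idx in enumerate(member_sheets):
            if pos == 0 or rng.random() < config.exact_duplicate_fraction:
                header = first_header
            else:
                header = draw(1)[0]
            specs[sheet_idx].append((header, vocab))
            members.add((sheet_ids[sheet_idx], header))
            add_entry(header, signature)
        for word in own_values:
            add_entry(word, signature)
        truth_groups.append(members)

    for _ in range(config.n_distractors):
        sheet_idx = rng.randrange(config.n_sheets)
        header = draw(1)[0]
        vocab = draw(_VALUES_PER_DISTRACTOR)
        specs[sheet_idx].append((header, vocab))
        truth_groups.append({(sheet_ids[sheet_idx], header)})
        add_entry(header, signature=None)
        for word in vocab:
            add_entry(word, signature=None)

    sheets: list[Spreadsheet] = []
    for sheet_idx, sheet_specs in enumerate(specs):
        if not sheet_specs:
            continue  # a spreadsheet must have at least one column
        rng.shuffle(sheet_specs)
        columns = []
        for col_idx, (header, vocab) in enumerate(sheet_specs):
            values = tuple(rng.choice(vocab) for _ in range(config.n_rows))
            columns.append(
                Column(
                    index=col_idx,
                    header=header,
                    values=values,
                    datatype=classify_datatype(values),
                )
            )
        sheets.append(Spreadsheet(sheet_id=sheet_ids[sheet_idx], columns=tuple(columns)))

    present = {(s.sheet_id, c.header) for s in sheets for c in s.columns}
    truth = MergePlan(
        MergeGroup(label=choose_label(g), members=frozenset(g))
        for g in truth_groups
        if g <= present
    )
    return sheets, CollocateLexicon(entries=entries), truth


def worked_example_fixture() -> tuple[list[Spreadsheet], CollocateLexicon, MergePlan]:
    """The two-sheet gender/sex/grade example with its collocate lexicon.

    Sheet A has one discrete column (gender: male, female); sheet B has two
    (sex: male, female; grade: moderate, poor, well).  The lexicon holds the
    packaged collocate lists for gender/female/male plus declared entries
    that give "sex" the same collocates as "gender" and give the grade terms
    vocabulary disjoint from the gender context, so gender~sex scores well
    above the 0.5 merging threshold and gender~grade well below it.
    """

    def col(index: int, header: str, values: tuple[str, ...]) -> Column:
        return Column(index, header, values, classify_datatype(values))

    sheet_a = Spreadsheet("A", (col(0, "gender", ("male", "female")),))
    sheet_b = Spreadsheet(
        "B",
        (
            col(0, "sex", ("male", "female", "")),
            col(1, "grade", ("moderate", "poor", "well")),
        ),
    )
    base = load_lexicon(GENDER_COLLOCATES)
    declared = {
        "sex": base.entries["gender"],
        "grade": ("point", "average", "school", "level"),
        "moderate": ("severe", "mild"),
        "poor": ("rich", "quality"),
        "well": ("water", "deep"),
    }
    lex = CollocateLexicon(entries={**base.entries, **declared})
    truth = MergePlan(
        [
            MergeGroup(label="sex", members=frozenset({("A", "gender"), ("B", "sex")})),
            MergeGroup(label="grade", members=frozenset({("B", "grade")})),
        ]
    )
    return [sheet_a, sheet_b], lex, truth


def write_fixture(
    out_dir: str | Path,
    sheets: list[Spreadsheet],
    lex: CollocateLexicon,
    truth: MergePlan,
) -> None:
    """Materialize a fixture as CSVs, a lexicon TSV, and a truth plan JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sheet in sheets:
        write_csv(sheet, out_dir / f"{sheet.sheet_id}.csv")
    save_lexicon(lex, out_dir / "lexicon.tsv")
    save_plan(truth, out_dir / "truth.json")
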