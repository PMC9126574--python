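"""Encoding of subjects into categorical item sets for rule mining.

Each subject becomes one transaction over a fixed vocabulary:

* age dichotomised at the sample-design median: ``age_ge70`` (inclusive)
  vs ``age_lt70``;
* one sex item (``male`` / ``female``) — both levels are encodable, so
  rules with either sex as consequent can be mined;
* one education item: ``educ_illiterate`` (0 years), ``educ_1_4``,
  ``educ_ge5``;
* a presence item per positive clinical-history flag (no negative
  items — rules use positive conditions only);
* ``cdr_gt_0_5`` iff CDR > 0.5 (strict), ``iqcode_ge_3_4`` iff
  IQCODE >= 3.4 (inclusive);
* ``microcephaly`` iff the stratified cutoff classifier fires.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import CLINICAL_FLAGS
from .cutoffs import CutoffTable, classify_cohort
from .errors import ParseError

__all__ = [
    "VOCABULARY",
    "Transaction",
    "encode_transaction",
    "encode_cohort",
    "write_basket",
    "read_basket",
    "transactions_to_onehot",
]

ITEM_MICROCEPHALY = "microcephaly"

#: Mutually exclusive item groups (exactly one item of each per subject).
EXCLUSIVE_GROUPS: dict[str, tuple[str, ...]] = {
    "age": ("age_ge70", "age_lt70"),
    "sex": ("male", "female"),
    "education": ("educ_illiterate", "educ_1_4", "educ_ge5"),
}

VOCABULARY: frozenset[str] = frozenset(
    [
        *EXCLUSIVE_GROUPS["age"],
        *EXCLUSIVE_GROUPS["sex"],
        *EXCLUSIVE_GROUPS["education"],
        *CLINICAL_FLAGS,
        "cdr_gt_0_5",
        "iqcode_ge_3_4",
        ITEM_MICROCEPHALY,
    ]
)


@dataclass(frozen=True)
class Transaction:
    subject_id: str
    items: frozenset[str]


def encode_transaction(subject, microcephaly_flag: bool) -> Transaction:
    """Encode one subject (mapping or DataFrame row) as an item set."""
    sex = str(subject["sex"])
    if sex not in EXCLUSIVE_GROUPS["sex"]:
        raise ParseError(
            f"unknown sex code {sex!r}; accepted codes are 'male' and 'female'"
        )
    items = set()
    items.add("age_ge70" if float(subject["age"]) >= 70.0 else "age_lt70")
    items.add(sex)
    edu = float(subject["education_years"])
    if edu == 0:
        items.add("educ_illiterate")
    elif edu < 5:
        items.add("educ_1_4")
    else:
        items.add("educ_ge5")
    for flag in CLINICAL_FLAGS:
        if int(subject[flag]):
            items.add(flag)
    if float(subject["cdr"]) > 0.5:
        items.add("cdr_gt_0_5")
    if float(subject["iqcode"]) >= 3.4:
        items.add("iqcode_ge_3_4")
    if microcephaly_flag:
        items.add(ITEM_MICROCEPHALY)
    return Transaction(subject_id=str(subject["subject_id"]), items=frozenset(items))


def encode_cohort(cohort: pd.DataFrame, cutoff_table: CutoffTable) -> list[Transaction]:
    """Classify microcephaly then encode every subject, in input order."""
    flags = classify_cohort(cohort, cutoff_table)
    return [
        encode_transaction(row, bool(flags[i]))
        for i, (_, row) in enumerate(cohort.iterrows())
    ]


def write_basket(transactions: list[Transaction], path) -> None:
    """Basket format: one line per subject, tab-separated sorted items."""
    with open(path, "w", encoding="utf-8") as fh:
        for t in transactions:
            fh.write("\t".join(sorted(t.items)) + "\n")


def read_basket(path) -> list[frozenset[str]]:
    """Read a basket file into a list of item sets (order preserved)."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            out.append(frozenset(line.split("\t")) if line else frozenset())
    return out


def transactions_to_onehot(transactions: list[Transaction]) -> pd.DataFrame:
    """One-hot export: one 0/1 column per vocabulary item, rows in order."""
    columns = sorted(VOCABULARY)
    data = {
        "subject_id": [t.subject_id for t in transactions],
        **{
            item: [int(item in t.items) for t in transactions] for item in columns
        },
    }
    return pd.DataFrame(data, columns=["subject_id", *columns])
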