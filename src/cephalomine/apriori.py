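"""From-scratch Apriori mining: frequent itemsets and association rules.

A rule X ⇒ Y over a transaction database of N records is scored by

* support    = occ(X ∪ Y) / N            (joint frequency),
* confidence = occ(X ∪ Y) / occ(X)       (conditional frequency),
* lift       = confidence / (occ(Y)/N)   (observed over independent).

Lift is on the probability scale: 1 means X and Y are independent,
values above/below 1 positive/negative association. Consequents are
single items; a rule of size k has k − 1 items in the antecedent.

Frequent itemsets are generated level-wise with the anti-monotone
prune: size-k candidates are lexicographic joins of frequent (k−1)-sets
sharing a (k−2)-prefix, kept only if every (k−1)-subset is frequent,
then counted by a transaction scan. Both the support and the confidence
thresholds are inclusive (>=).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .errors import ConfigError, StatisticError

__all__ = [
    "MiningConfig",
    "Itemset",
    "AssociationRule",
    "support_count",
    "apriori_frequent_itemsets",
    "generate_rules",
    "lift_from_confidence",
    "mine",
    "sort_rules",
]


@dataclass(frozen=True)
class MiningConfig:
    """Thresholds for the miner.

    min_support and min_confidence are proportions; max_rule_size
    bounds |X| + |Y|. The consequent is always a single item.
    """

    min_support: float = 0.01
    min_confidence: float = 0.30
    max_rule_size: int = 3

    #: fixed by design: rules have exactly one consequent item
    consequent_size: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.min_support <= 1.0:
            raise ConfigError(f"min_support must be in (0, 1], got {self.min_support}")
        if not 0.0 <= self.min_confidence <= 1.0:
            raise ConfigError(
                f"min_confidence must be in [0, 1], got {self.min_confidence}"
            )
        if self.max_rule_size < 2:
            raise ConfigError(f"max_rule_size must be >= 2, got {self.max_rule_size}")
        if self.consequent_size != 1:
            raise ConfigError("consequent_size is fixed at 1")


@dataclass(frozen=True)
class Itemset:
    """A nonempty item combination with its occurrence count."""

    items: tuple[str, ...]  # sorted
    occ: int

    def support(self, n: int) -> float:
        return self.occ / n


@dataclass(frozen=True)
class AssociationRule:
    """X ⇒ y with exact counts and derived metrics."""

    antecedent: tuple[str, ...]  # sorted
    consequent: str
    occ_x: int
    occ_y: int
    occ_xy: int
    n: int

    @property
    def support(self) -> float:
        return self.occ_xy / self.n

    @property
    def confidence(self) -> float:
        return self.occ_xy / self.occ_x

    @property
    def lift(self) -> float:
        return (self.occ_xy * self.n) / (self.occ_x * self.occ_y)

    @property
    def size(self) -> int:
        return len(self.antecedent) + 1

    def to_dict(self) -> dict:
        return {
            "antecedent": list(self.antecedent),
            "consequent": self.consequent,
            "occ_x": self.occ_x,
            "occ_y": self.occ_y,
            "occ_xy": self.occ_xy,
            "n": self.n,
            "support": self.support,
            "confidence": self.confidence,
            "lift": self.lift,
        }


def _as_sets(transactions) -> list[frozenset[str]]:
    out = []
    for t in transactions:
        out.append(frozenset(t.items) if hasattr(t, "items") and not isinstance(t, dict) else frozenset(t))
    if not out:
        raise StatisticError("transaction database is empty")
    return out


def support_count(items, transactions) -> tuple[int, float]:
    """Occurrences of an item combination and its support proportion."""
    db = _as_sets(transactions)
    target = frozenset(items)
    count = sum(1 for t in db if target <= t)
    return count, count / len(db)


def apriori_frequent_itemsets(
    transactions, config: MiningConfig
) -> list[Itemset]:
    """All itemsets of size 1..max_rule_size with support >= min_support.

    Returned sorted by (size, items). Level-wise generation: candidates
    of size k come only from frequent (k−1)-sets (anti-monotone prune).
    """
    db = _as_sets(transactions)
    n = len(db)
    min_occ = config.min_support * n

    counts: dict[tuple[str, ...], int] = {}
    singles: dict[str, int] = {}
    for t in db:
        for item in t:
            singles[item] = singles.get(item, 0) + 1
    level = []
    for item in sorted(singles):
        if singles[item] >= min_occ:
            counts[(item,)] = singles[item]
            level.append((item,))

    result: list[Itemset] = [Itemset(k, counts[k]) for k in level]
    for _size in range(2, config.max_rule_size + 1):
        candidates = _join_candidates(level)
        candidates = [
            c
            for c in candidates
            if all(tuple(sub) in counts for sub in combinations(c, len(c) - 1))
        ]
        if not candidates:
            break
        cand_counts = {c: 0 for c in candidates}
        cand_sets = {c: frozenset(c) for c in candidates}
        for t in db:
            for c in candidates:
                if cand_sets[c] <= t:
                    cand_counts[c] += 1
        level = []
        for c in sorted(candidates):
            if cand_counts[c] >= min_occ:
                counts[c] = cand_counts[c]
                level.append(c)
                result.append(Itemset(c, cand_counts[c]))
        if not level:
            break
    return result


def _join_candidates(level: list[tuple[str, ...]]) -> list[tuple[str, ...]]:
    """Lexicographic join of sorted k-sets sharing a (k−1)-prefix."""
    out = []
    level = sorted(level)
    for i, a in enumerate(level):
        for b in level[i + 1 :]:
            if a[:-1] != b[:-1]:
                break
            out.append((*a, b[-1]))
    return out


def generate_rules(
    frequent_itemsets: list[Itemset], transactions, config: MiningConfig
) -> list[AssociationRule]:
    """Emit every single-consequent rule with confidence >= min_confidence.

    For each frequent itemset S with |S| >= 2 and each choice of
    consequent y in S, the antecedent S \\ {y} is itself frequent (by
    anti-monotonicity) so all counts are exact and already available.
    """
    db = _as_sets(transactions)
    n = len(db)
    occ = {fi.items: fi.occ for fi in frequent_itemsets}
    for items in occ:
        if len(items) > config.max_rule_size:
            raise ConfigError(
                f"itemset {items} larger than max_rule_size={config.max_rule_size}"
            )
    # Consequent supports may fall below min_support for the antecedent
    # side of lift; count single items directly when missing.
    singles: dict[str, int] = {}

    def occ_of(items: tuple[str, ...]) -> int:
        if items in occ:
            return occ[items]
        if len(items) == 1:
            item = items[0]
            if item not in singles:
                singles[item] = sum(1 for t in db if item in t)
            return singles[item]
        target = frozenset(items)
        return sum(1 for t in db if target <= t)

    rules = []
    for itemset in frequent_itemsets:
        if len(itemset.items) < 2:
            continue
        for consequent in itemset.items:
            antecedent = tuple(i for i in itemset.items if i != consequent)
            occ_x = occ_of(antecedent)
            occ_y = occ_of((consequent,))
            confidence = itemset.occ / occ_x
            if confidence >= config.min_confidence:
                rules.append(
                    AssociationRule(
                        antecedent=antecedent,
                        consequent=consequent,
                        occ_x=occ_x,
                        occ_y=occ_y,
                        occ_xy=itemset.occ,
                        n=n,
                    )
                )
    return sort_rules(rules)


def sort_rules(rules: list[AssociationRule]) -> list[AssociationRule]:
    """Canonical order: lift desc, confidence desc, support desc, then
    lexicographic antecedent and consequent."""
    return sorted(
        rules,
        key=lambda r: (-r.lift, -r.confidence, -r.support, r.antecedent, r.consequent),
    )


def lift_from_confidence(confidence: float, consequent_support: float) -> float:
    """Lift from a rule's confidence and its consequent's support."""
    if not 0.0 < consequent_support <= 1.0:
        raise StatisticError(
            f"consequent support must be in (0, 1], got {consequent_support}"
        )
    return confidence / consequent_support


def mine(transactions, config: MiningConfig | None = None) -> list[AssociationRule]:
    """Convenience wrapper: frequent itemsets then rules, sorted."""
    config = config or MiningConfig()
    itemsets = apriori_frequent_itemsets(transactions, config)
    return generate_rules(itemsets, transactions, config)
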