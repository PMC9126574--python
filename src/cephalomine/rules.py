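"""Post-mining analysis around a focus item (microcephaly by default).

Select the rules that mention the focus item, rank them by lift, and
build with-vs-without comparisons: for each rule whose antecedent pairs
the focus item with one other condition, find the same rule with the
focus item removed and report the confidence/lift deltas. Counterparts
that were not emitted by the miner (because they miss a threshold) are
recomputed directly from transaction counts and flagged sub-threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

from .apriori import AssociationRule, MiningConfig, sort_rules, support_count
from .errors import CephalomineError

__all__ = [
    "RuleComparison",
    "filter_rules_containing",
    "rank_by_lift",
    "compare_with_without",
    "rules_to_tsv",
    "report",
]

logger = logging.getLogger(__name__)


def filter_rules_containing(
    rules: list[AssociationRule], item: str
) -> list[AssociationRule]:
    """Rules whose antecedent or consequent contains ``item``; order kept."""
    selected = [r for r in rules if item in r.antecedent or item == r.consequent]
    if rules and not selected:
        logger.warning("no rule mentions item %r", item)
    return selected


def rank_by_lift(rules: list[AssociationRule]) -> list[AssociationRule]:
    """Stable canonical ranking (lift desc, then confidence, support)."""
    return sort_rules(rules)


@dataclass(frozen=True)
class RuleComparison:
    """A focus rule paired with its counterpart minus the focus item."""

    rule_with: AssociationRule
    rule_without: AssociationRule
    without_sub_threshold: bool  # counterpart recomputed, not mined

    @property
    def delta_confidence(self) -> float:
        return self.rule_with.confidence - self.rule_without.confidence

    @property
    def delta_lift(self) -> float:
        return self.rule_with.lift - self.rule_without.lift

    @property
    def higher_with_item(self) -> bool:
        """Whether both confidence and lift rise when the item is present."""
        return self.delta_confidence > 0 and self.delta_lift > 0

    def to_dict(self) -> dict:
        return {
            "rule_with": self.rule_with.to_dict(),
            "rule_without": self.rule_without.to_dict(),
            "delta_confidence": self.delta_confidence,
            "delta_lift": self.delta_lift,
            "without_sub_threshold": self.without_sub_threshold,
            "higher_with_item": self.higher_with_item,
        }


def compare_with_without(
    rules: list[AssociationRule],
    transactions,
    item: str,
    config: MiningConfig | None = None,
) -> list[RuleComparison]:
    """Pair each size-3 focus rule with its focus-free counterpart.

    Applies to rules with ``item`` in a two-item antecedent. The
    counterpart keeps the consequent and drops ``item``; if absent from
    ``rules`` its metrics are recomputed from raw counts and flagged.
    """
    config = config or MiningConfig()
    mined = {(r.antecedent, r.consequent): r for r in rules}
    comparisons = []
    for rule in rules:
        if item not in rule.antecedent or len(rule.antecedent) != 2:
            continue
        reduced = tuple(i for i in rule.antecedent if i != item)
        key = (reduced, rule.consequent)
        if key in mined:
            counterpart = mined[key]
            sub = False
        else:
            counterpart = _rule_from_counts(reduced, rule.consequent, transactions)
            sub = (
                counterpart.support < config.min_support
                or counterpart.confidence < config.min_confidence
            )
        comparisons.append(
            RuleComparison(
                rule_with=rule, rule_without=counterpart, without_sub_threshold=sub
            )
        )
    return comparisons


def _rule_from_counts(
    antecedent: tuple[str, ...], consequent: str, transactions
) -> AssociationRule:
    occ_x, _ = support_count(antecedent, transactions)
    occ_y, _ = support_count((consequent,), transactions)
    occ_xy, _ = support_count((*antecedent, consequent), transactions)
    n = len(list(transactions))
    if occ_x == 0:
        raise CephalomineError(
            f"antecedent {antecedent} never occurs; counterpart undefined"
        )
    return AssociationRule(
        antecedent=antecedent, consequent=consequent,
        occ_x=occ_x, occ_y=occ_y, occ_xy=occ_xy, n=n,
    )


_TSV_HEADER = "antecedent\tconsequent\tocc_x\tocc_y\tocc_xy\tn\tsupport\tconfidence\tlift"


def rules_to_tsv(rules: list[AssociationRule], path) -> None:
    """Full-precision TSV export (antecedent comma-joined, sorted)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_TSV_HEADER + "\n")
        for r in rules:
            fh.write(
                f"{','.join(r.antecedent)}\t{r.consequent}\t{r.occ_x}\t{r.occ_y}\t"
                f"{r.occ_xy}\t{r.n}\t{r.support!r}\t{r.confidence!r}\t{r.lift!r}\n"
            )


def _format_rule(r: AssociationRule) -> str:
    return (
        f"IF {' AND '.join(r.antecedent)} THEN {r.consequent}  "
        f"(support {100 * r.support:.1f}%, confidence {100 * r.confidence:.1f}%, "
        f"lift {r.lift:.1f})"
    )


def report(
    rules: list[AssociationRule],
    comparisons: list[RuleComparison],
    out_dir,
) -> dict:
    """Render ranked rule tables (sizes 2 and 3 separately) plus the
    with-vs-without comparison, as ``report.txt`` and ``report.json``.

    Percentages and lifts are rounded to one decimal in the text
    rendering only; the JSON mirror keeps full precision. Output is
    byte-stable for fixed input. Returns the JSON payload.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ranked = rank_by_lift(rules)
    size2 = [r for r in ranked if r.size == 2]
    size3 = [r for r in ranked if r.size == 3]

    lines = ["# Ranked rules of size three", ""]
    lines += [_format_rule(r) for r in size3] or ["(none)"]
    lines += ["", "# Ranked rules of size two", ""]
    lines += [_format_rule(r) for r in size2] or ["(none)"]
    lines += ["", "# With-vs-without comparison", ""]
    if comparisons:
        for c in comparisons:
            flag = "  [sub-threshold counterpart]" if c.without_sub_threshold else ""
            lines.append("with:    " + _format_rule(c.rule_with))
            lines.append("without: " + _format_rule(c.rule_without) + flag)
            lines.append(
                f"delta:   confidence {c.delta_confidence:+.3f}, "
                f"lift {c.delta_lift:+.2f}, "
                f"higher with item: {c.higher_with_item}"
            )
            lines.append("")
    else:
        lines.append("(none)")
    (out_dir / "report.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")

    payload = {
        "rules_size3": [r.to_dict() for r in size3],
        "rules_size2": [r.to_dict() for r in size2],
        "comparisons": [c.to_dict() for c in comparisons],
    }
    with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return payload
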