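"""End-to-end orchestration: simulate/ingest → screen → cutoffs →
classify → encode → mine → report, with a manifest of content hashes.

Every stage logs its funnel counts (subjects, strata, frequent
itemsets, rules, focus rules) so the narrowing from the full rule set
to the focus rules is visible. A rerun with the same config and seed is
byte-identical, manifest included.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .apriori import MiningConfig, apriori_frequent_itemsets, generate_rules
from .cohort import GeneratorConfig, generate_cohort, read_cohort, write_cohort
from .cutoffs import DEFAULT_BIN_EDGES, build_cutoff_table, classify_cohort
from .errors import CephalomineError, ConfigError
from .rules import compare_with_without, filter_rules_containing, report, rules_to_tsv
from .screening import screen_variables
from .transactions import VOCABULARY, encode_cohort, write_basket

__all__ = ["PipelineConfig", "run_pipeline", "make_fixtures"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one pipeline run needs.

    Either ``cohort_path`` (ingest a CSV) or ``generator`` (simulate)
    must be set; ``seed`` overrides the generator's seed so one knob
    controls all randomness.
    """

    out_dir: str | Path
    cohort_path: str | Path | None = None
    generator: GeneratorConfig | None = None
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    mining: MiningConfig = field(default_factory=MiningConfig)
    focus_item: str = "microcephaly"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.cohort_path is None) == (self.generator is None):
            raise ConfigError("set exactly one of cohort_path or generator")
        if self.focus_item not in VOCABULARY:
            raise ConfigError(
                f"focus item {self.focus_item!r} not in the item vocabulary"
            )


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except CephalomineError as exc:
                raise CephalomineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis; returns the artifact directory.

    Artifacts: cohort.csv (if simulated), screening.json, cutoffs.csv,
    cohort_flagged.csv, transactions.basket, rules.tsv, rules.json,
    report/ (txt + json), manifest.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    if config.generator is not None:
        gen = dataclasses.replace(config.generator, seed=config.seed)
        cohort = _stage("simulate")(generate_cohort)(gen)
        write_cohort(cohort, out / "cohort.csv")
        artifacts.append(out / "cohort.csv")
    else:
        cohort = _stage("ingest")(read_cohort)(config.cohort_path)
    logger.info("cohort: %d subjects", len(cohort))

    screening = _stage("screen")(screen_variables)(cohort)
    with open(out / "screening.json", "w", encoding="utf-8") as fh:
        json.dump(screening.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    artifacts.append(out / "screening.json")
    logger.info("screening: significant = %s", sorted(screening.significant))

    table = _stage("cutoffs")(build_cutoff_table)(cohort, config.bin_edges)
    table.write_csv(out / "cutoffs.csv")
    artifacts.append(out / "cutoffs.csv")
    logger.info("cutoffs: %d strata", len(table.strata))

    flags = _stage("classify")(classify_cohort)(cohort, table)
    flagged = cohort.copy()
    flagged["microcephaly"] = flags
    flagged.to_csv(out / "cohort_flagged.csv", index=False)
    artifacts.append(out / "cohort_flagged.csv")
    logger.info("classified: %d/%d microcephalic", int(flags.sum()), len(flags))

    txns = _stage("encode")(encode_cohort)(cohort, table)
    write_basket(txns, out / "transactions.basket")
    artifacts.append(out / "transactions.basket")

    itemsets = _stage("mine")(apriori_frequent_itemsets)(txns, config.mining)
    all_rules = _stage("mine")(generate_rules)(itemsets, txns, config.mining)
    rules_to_tsv(all_rules, out / "rules.tsv")
    with open(out / "rules.json", "w", encoding="utf-8") as fh:
        json.dump([r.to_dict() for r in all_rules], fh, indent=2, sort_keys=True)
        fh.write("\n")
    artifacts += [out / "rules.tsv", out / "rules.json"]
    logger.info(
        "mining: %d frequent itemsets, %d rules", len(itemsets), len(all_rules)
    )

    focus_rules = filter_rules_containing(all_rules, config.focus_item)
    comparisons = _stage("report")(compare_with_without)(
        focus_rules, txns, config.focus_item, config.mining
    )
    _stage("report")(report)(focus_rules, comparisons, out / "report")
    artifacts += [out / "report" / "report.txt", out / "report" / "report.json"]
    logger.info(
        "focus %r: %d rules, %d comparisons",
        config.focus_item, len(focus_rules), len(comparisons),
    )

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "artifacts": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(artifacts)
        },
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["out_dir"] = str(d["out_dir"])
    if d["cohort_path"] is not None:
        d["cohort_path"] = str(d["cohort_path"])
    d["bin_edges"] = list(d["bin_edges"])
    return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


#: The worked toy database used throughout the miner's documentation.
TOY_DB = [{"A", "B"}, {"A"}, {"B"}, {"A", "B", "C"}]


def make_fixtures(out_dir) -> Path:
    """Write small hand-checkable datasets for tests and examples.

    * ``toy.basket`` — the four-transaction database [{A,B},{A},{B},{A,B,C}];
    * ``mini_cohort.csv`` — a 50-subject simulated cohort;
    * ``mini_cutoffs.csv`` — its cutoff table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "toy.basket", "w", encoding="utf-8") as fh:
        for t in TOY_DB:
            fh.write("\t".join(sorted(t)) + "\n")
    # seed chosen so every nonempty sex x height stratum has n >= 2
    cohort = generate_cohort(GeneratorConfig(n_subjects=50, seed=2))
    write_cohort(cohort, out / "mini_cohort.csv")
    build_cutoff_table(cohort).write_csv(out / "mini_cutoffs.csv")
    return out
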