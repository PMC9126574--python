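"""Shared fixtures: reference cohorts and the brute-force miner oracle.

The brute-force functions enumerate every candidate itemset and rule
without any pruning or shared counting; they are deliberately
independent of the package's level-wise implementation so they can
serve as an oracle on small databases.
"""

from itertools import combinations

import pytest

from cephalomine import GeneratorConfig, build_cutoff_table, generate_cohort

TOY_DB = [{"A", "B"}, {"A"}, {"B"}, {"A", "B", "C"}]


def brute_force_itemsets(db, min_support, max_size):
    """Every itemset (size 1..max_size) with support >= min_support,
    found by exhaustive enumeration over all item combinations."""
    items = sorted({i for t in db for i in t})
    n = len(db)
    out = {}
    for size in range(1, max_size + 1):
        for combo in combinations(items, size):
            occ = sum(1 for t in db if set(combo) <= t)
            if occ / n >= min_support:
                out[combo] = occ
    return out


def brute_force_rules(db, min_support, min_confidence, max_size):
    """Every single-consequent rule from the brute-force itemsets whose
    confidence >= min_confidence. Returns {(antecedent, consequent):
    (occ_x, occ_y, occ_xy)}."""
    freq = brute_force_itemsets(db, min_support, max_size)
    n = len(db)
    rules = {}
    for itemset, occ_xy in freq.items():
        if len(itemset) < 2:
            continue
        for consequent in itemset:
            antecedent = tuple(i for i in itemset if i != consequent)
            occ_x = sum(1 for t in db if set(antecedent) <= t)
            occ_y = sum(1 for t in db if consequent in t)
            if occ_xy / occ_x >= min_confidence:
                rules[(antecedent, consequent)] = (occ_x, occ_y, occ_xy)
    return rules


def random_database(rng, max_items=8, max_transactions=50):
    """A random small transaction database plus random thresholds."""
    n_items = rng.integers(2, max_items + 1)
    items = [f"i{k}" for k in range(n_items)]
    n_txn = rng.integers(1, max_transactions + 1)
    db = []
    for _ in range(n_txn):
        p = rng.uniform(0.1, 0.8)
        t = {i for i in items if rng.random() < p}
        db.append(t)
    min_support = float(rng.uniform(0.02, 0.6))
    min_confidence = float(rng.uniform(0.0, 0.9))
    max_size = int(rng.integers(2, 5))
    return db, min_support, min_confidence, max_size


@pytest.fixture(scope="session")
def default_cohort():
    """One realistic-scale simulated cohort shared across tests."""
    return generate_cohort(GeneratorConfig(n_subjects=2508, seed=1))


@pytest.fixture(scope="session")
def default_cutoffs(default_cohort):
    return build_cutoff_table(default_cohort)


@pytest.fixture()
def toy_db():
    return [set(t) for t in TOY_DB]
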