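"""Mine association rules from the encoded cohort.

Subjects become transactions over categorical items (age >= 70, sex,
education level, comorbidities, CDR > 0.5, IQCODE >= 3.4,
microcephaly). Apriori finds frequent itemsets at 1% minimum support,
then emits single-consequent rules at 30% minimum confidence, rule size
at most three.
"""

from cephalomine import (
    GeneratorConfig,
    MiningConfig,
    build_cutoff_table,
    encode_cohort,
    generate_cohort,
    mine,
)

cohort = generate_cohort(GeneratorConfig(n_subjects=2508, seed=1))
table = build_cutoff_table(cohort)
txns = encode_cohort(cohort, table)
rules = mine(txns, MiningConfig(min_support=0.01, min_confidence=0.30, max_rule_size=3))

print(f"{len(rules)} rules mined from {len(txns)} transactions\n")
print("top five by lift:")
for r in rules[:5]:
    print(
        f"  IF {' AND '.join(r.antecedent)} THEN {r.consequent}"
        f"  (conf {100 * r.confidence:.1f}%, lift {r.lift:.1f})"
    )

# Lift > 1 means the antecedent and consequent co-occur more often than
# independence predicts; the cognitive-screening items (CDR, IQCODE)
# dominate the top of the ranking because they flag the same latent
# impairment state.
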