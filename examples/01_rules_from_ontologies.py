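"""Derive correspondence rules and inconsistency patterns from ontologies.

Builds a small synthetic GO-like ontology (with positively_regulates /
negatively_regulates logical definitions) and a phenotype ontology (with
Entity-Quality definitions), then joins them into rules and their mirrored
inconsistency patterns.
"""

from phenorules import (
    build_correspondence_rules,
    build_inconsistency_patterns,
    decompose_all,
    index_regulations,
)
from phenorules.fixtures import FixtureSpec, default_quality_config, make_toy_ontologies

go, pheno, _ = make_toy_ontologies(FixtureSpec(n_processes=10, n_regulators_pos=4,
                                               n_regulators_neg=4, seed=1))
regs = index_regulations(go)
decs = decompose_all(pheno, default_quality_config())
rules = build_correspondence_rules(regs, decs)
patterns = build_inconsistency_patterns(regs, decs)

print(f"{len(regs)} regulation axioms, {len(decs)} EQ phenotype definitions")
print(f"-> {len(rules)} correspondence rules, {len(patterns)} inconsistency patterns")
print("\nfirst three rules (function class -> phenotype under loss of function):")
for rule in rules[:3]:
    print(f"  {rule.function_class} -> {rule.phenotype_class}  [{rule.rule_kind}]")
# inc_dec: losing a positive regulator decreases the target process rate;
# dec_inc: losing a negative regulator increases it; abnormal: losing any
# participant makes the process abnormal.
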