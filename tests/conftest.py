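"""Shared fixtures: tiny hand-written ontologies and generated corpora."""

from __future__ import annotations

import random

import pytest

from phenorules.fixtures import (
    FixtureSpec,
    default_quality_config,
    make_annotation_corpora,
    make_toy_ontologies,
)
from phenorules.ontology import parse_obo
from phenorules.rules import (
    build_correspondence_rules,
    build_inconsistency_patterns,
    decompose_all,
    index_regulations,
)

# Worked-example ontology: real GO/MP identifiers for the three canonical
# audit cases —
#   Fnip1: positive regulation of B cell apoptotic process (GO:0002904)
#          vs increased B cell apoptosis (MP:0008782)
#   Gpc3:  negative regulation of growth (GO:0045926)
#          vs a decreased-growth phenotype
#   BAG6:  negative regulation of apoptotic process (GO:0043066)
#          vs decreased apoptosis (MP:0006043), asserted at the subclass
#          decreased susceptibility to neuronal excitotoxicity (MP:0008236)
WORKED_GO_OBO = """\
format-version: 1.2

[Typedef]
id: positively_regulates
name: positively_regulates

[Typedef]
id: negatively_regulates
name: negatively_regulates

[Term]
id: GO:0008150
name: biological_process

[Term]
id: GO:0065007
name: biological regulation
is_a: GO:0008150

[Term]
id: GO:0001783
name: B cell apoptotic process
is_a: GO:0008150

[Term]
id: GO:0006915
name: apoptotic process
is_a: GO:0008150

[Term]
id: GO:0040007
name: growth
is_a: GO:0008150

[Term]
id: GO:0070242
name: thymocyte apoptotic process
is_a: GO:0006915

[Term]
id: GO:0002904
name: positive regulation of B cell apoptotic process
is_a: GO:0065007
intersection_of: GO:0065007
intersection_of: positively_regulates GO:0001783

[Term]
id: GO:0043066
name: negative regulation of apoptotic process
is_a: GO:0065007
intersection_of: GO:0065007
intersection_of: negatively_regulates GO:0006915

[Term]
id: GO:0045926
name: negative regulation of growth
is_a: GO:0065007
intersection_of: GO:0065007
intersection_of: negatively_regulates GO:0040007
"""

WORKED_PHENO_OBO = """\
format-version: 1.2

[Typedef]
id: phenotype_of
name: phenotype_of

[Typedef]
id: has_quality
name: has_quality

[Term]
id: MP:0000001
name: mammalian phenotype

[Term]
id: PATO:0000001
name: quality

[Term]
id: PATO:0000912
name: increased rate
is_a: PATO:0000001

[Term]
id: PATO:0000911
name: decreased rate
is_a: PATO:0000001

[Term]
id: PATO:0000460
name: abnormal
is_a: PATO:0000001

[Term]
id: MP:0008782
name: increased B cell apoptosis
is_a: MP:0000001
intersection_of: MP:0000001
intersection_of: phenotype_of GO:0001783
intersection_of: has_quality PATO:0000912
intersection_of: has_quality PATO:0000460

[Term]
id: MP:0006043
name: decreased apoptosis
is_a: MP:0000001
intersection_of: MP:0000001
intersection_of: phenotype_of GO:0006915
intersection_of: has_quality PATO:0000911
intersection_of: has_quality PATO:0000460

[Term]
id: MP:0008236
name: decreased susceptibility to neuronal excitotoxicity
is_a: MP:0006043

[Term]
id: MP:0001732
name: postnatal growth retardation
is_a: MP:0000001
intersection_of: MP:0000001
intersection_of: phenotype_of GO:0040007
intersection_of: has_quality PATO:0000911
intersection_of: has_quality PATO:0000460

[Term]
id: MP:0009541
name: increased thymocyte apoptosis
is_a: MP:0000001
intersection_of: MP:0000001
intersection_of: phenotype_of GO:0070242
intersection_of: has_quality PATO:0000912
intersection_of: has_quality PATO:0000460
"""


@pytest.fixture(scope="session")
def worked_go():
    return parse_obo(WORKED_GO_OBO.splitlines())


@pytest.fixture(scope="session")
def worked_pheno():
    return parse_obo(WORKED_PHENO_OBO.splitlines())


@pytest.fixture(scope="session")
def worked_quality_config():
    return default_quality_config()


@pytest.fixture(scope="session")
def worked_rules(worked_go, worked_pheno, worked_quality_config):
    regs = index_regulations(worked_go)
    decs = decompose_all(worked_pheno, worked_quality_config)
    return build_correspondence_rules(regs, decs)


@pytest.fixture(scope="session")
def worked_patterns(worked_go, worked_pheno, worked_quality_config):
    regs = index_regulations(worked_go)
    decs = decompose_all(worked_pheno, worked_quality_config)
    return build_inconsistency_patterns(regs, decs)


@pytest.fixture(scope="session")
def toy():
    """Default-scale generated fixture bundle (no planted noise)."""
    spec = FixtureSpec(n_genes=50, annotation_noise=0.0,
                       inconsistency_rate=0.2, seed=7)
    go, pheno, plant_log = make_toy_ontologies(spec)
    qc = default_quality_config()
    regs = index_regulations(go)
    decs = decompose_all(pheno, qc)
    rules = build_correspondence_rules(regs, decs)
    patterns = build_inconsistency_patterns(regs, decs)
    functions, phenotypes, truth_log = make_annotation_corpora(
        spec, go, pheno, rules, patterns)
    return {
        "spec": spec, "go": go, "pheno": pheno, "plant_log": plant_log,
        "regs": regs, "decs": decs, "rules": rules, "patterns": patterns,
        "functions": functions, "phenotypes": phenotypes,
        "truth_log": truth_log,
    }


def random_dag_obo(n: int, seed: int, prefix: str = "T") -> str:
    """A random n-class DAG serialized as OBO (acyclic by construction)."""
    rng = random.Random(seed)
    ids = [f"{prefix}:{i:07d}" for i in range(n)]
    lines = ["format-version: 1.2", ""]
    for i, cid in enumerate(ids):
        lines += ["[Term]", f"id: {cid}", f"name: class {i}"]
        if i:
            k = min(i, rng.choice((1, 1, 2)))
            for parent in sorted(rng.sample(ids[:i], k)):
                lines.append(f"is_a: {parent}")
        lines.append("")
    return "\n".join(lines) + "\n"
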