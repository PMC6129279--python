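"""Audit function/phenotype annotation pairs for rule violations.

Recreates the canonical audit case: a gene annotated with *positive
regulation of B cell apoptotic process* (GO:0002904) whose knockout is
annotated with *increased B cell apoptosis* (MP:0008782).  Losing an
activator should lower the rate, so the pair is flagged.
"""

import io

from phenorules import (
    AnnotationCorpus,
    GeneAnnotation,
    build_inconsistency_patterns,
    check_corpus,
    decompose_all,
    index_regulations,
    parse_obo,
)
from phenorules.fixtures import default_quality_config

GO_OBO = """\
format-version: 1.2

[Term]
id: GO:0065007
name: biological regulation

[Term]
id: GO:0001783
name: B cell apoptotic process

[Term]
id: GO:0002904
name: positive regulation of B cell apoptotic process
is_a: GO:0065007
intersection_of: GO:0065007
intersection_of: positively_regulates GO:0001783
"""

PHENO_OBO = """\
format-version: 1.2

[Term]
id: PATO:0000912
name: increased rate

[Term]
id: PATO:0000460
name: abnormal

[Term]
id: MP:0008782
name: increased B cell apoptosis
intersection_of: phenotype_of GO:0001783
intersection_of: has_quality PATO:0000912
intersection_of: has_quality PATO:0000460
"""

go = parse_obo(io.StringIO(GO_OBO))
pheno = parse_obo(io.StringIO(PHENO_OBO))
patterns = build_inconsistency_patterns(
    index_regulations(go), decompose_all(pheno, default_quality_config()))

functions = AnnotationCorpus()
functions.add("Fnip1", GeneAnnotation("GO:0002904", evidence="IMP"))
phenotypes = AnnotationCorpus()
phenotypes.add("Fnip1", GeneAnnotation("MP:0008782"))

findings = check_corpus(functions, phenotypes, patterns, mode="exact")
for f in findings:
    print(f"{f.gene}: {f.function_class} vs {f.phenotype_class} "
          f"violates {f.violated_rule} ({f.mode} match)")
# One finding: the function and phenotype annotations contradict each other,
# suggesting one of the two curated assertions has the wrong regulation sign.
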