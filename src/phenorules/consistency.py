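"""Flag gene-level annotation pairs that contradict the correspondence rules.

A gene is flagged when it simultaneously carries a function annotation and a
phenotype annotation forming an inconsistency pattern — e.g. *positive
regulation of B cell apoptotic process* together with *increased B cell
apoptosis* (loss of an activator should lower, not raise, the rate).

Two matching modes:

* ``exact`` — only directly asserted phenotype annotations match a pattern;
* ``inferred`` — additionally, an assertion to a strict subclass of the
  pattern's phenotype matches, with the asserted class recorded in
  ``inferred_via``.  Inferred matches are weaker evidence: an annotation to
  a specific subclass does not imply the general phenotype holds broadly,
  which is why exact mode is the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

from .annotations import AnnotationCorpus
from .ontology import OntologyGraph, descendants
from .rules import InconsistencyPattern

logger = logging.getLogger(__name__)

MODES = ("exact", "inferred")


@dataclass(frozen=True, order=True)
class InconsistencyFinding:
    gene: str
    function_class: str
    phenotype_class: str
    violated_rule: str
    mode: str  # how this pair matched: exact | inferred
    inferred_via: str | None = None

    def __post_init__(self) -> None:
        if self.mode == "exact" and self.inferred_via is not None:
            raise ValueError("exact finding must not carry inferred_via")


def check_corpus(
    functions: AnnotationCorpus,
    phenotypes: AnnotationCorpus,
    patterns: Sequence[InconsistencyPattern],
    mode: str = "exact",
    graph: OntologyGraph | None = None,
    function_side_inference: bool = False,
) -> list[InconsistencyFinding]:
    """Return all rule-violating (gene, function, phenotype) triples.

    Both corpora must hold direct (unclosed) assertions.  In ``inferred``
    mode ``graph`` is required; patterns whose phenotype class is absent from
    the graph are skipped for inference (with a warning) but still matched
    exactly.  ``function_side_inference`` additionally matches function
    annotations asserted to a strict subclass of the pattern's function
    class (off by default).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if functions.closed or phenotypes.closed:
        raise ValueError("check_corpus expects direct (unclosed) corpora")
    if mode == "inferred" and graph is None:
        raise ValueError("inferred mode requires an ontology graph")

    exact_pairs = {(p.function_class, p.phenotype_class): p for p in patterns}

    # inferred mode: map each asserted-phenotype candidate subclass back to
    # the pattern phenotype it descends from
    sub_index: dict[str, list[InconsistencyPattern]] = {}
    fn_sub_index: dict[str, list[InconsistencyPattern]] = {}
    if mode == "inferred":
        for p in patterns:
            if p.phenotype_class not in graph:
                logger.warning(
                    "pattern phenotype %s not in ontology; skipped for "
                    "inference", p.phenotype_class)
                continue
            for sub in descendants(graph, p.phenotype_class):
                if sub != p.phenotype_class:
                    sub_index.setdefault(sub, []).append(p)
        if function_side_inference:
            for p in patterns:
                if p.function_class not in graph:
                    continue
                for sub in descendants(graph, p.function_class):
                    if sub != p.function_class:
                        fn_sub_index.setdefault(sub, []).append(p)

    findings: dict[tuple[str, str, str], InconsistencyFinding] = {}

    def record(gene: str, pat: InconsistencyPattern, via: str | None) -> None:
        key = (gene, pat.function_class, pat.phenotype_class)
        if via is None:
            findings[key] = InconsistencyFinding(
                gene, pat.function_class, pat.phenotype_class,
                pat.violated_rule, "exact")
        elif key not in findings:  # exact match wins over inferred
            findings[key] = InconsistencyFinding(
                gene, pat.function_class, pat.phenotype_class,
                pat.violated_rule, "inferred", inferred_via=via)

    for gene in functions.genes & phenotypes.genes:
        fclasses = functions.classes_of(gene)
        pclasses = phenotypes.classes_of(gene)
        for f in fclasses:
            for ph in pclasses:
                pat = exact_pairs.get((f, ph))
                if pat is not None:
                    record(gene, pat, None)
                for p in sub_index.get(ph, ()):
                    if p.function_class == f:
                        record(gene, p, ph)
            for p in fn_sub_index.get(f, ()):
                for ph in pclasses:
                    if ph == p.phenotype_class:
                        record(gene, p, f)
                    elif ph in sub_index and p in sub_index[ph]:
                        record(gene, p, ph)
    return sorted(findings.values())


def write_findings_tsv(findings: Iterable[InconsistencyFinding], stream: IO[str]) -> None:
    stream.write(
        "gene\tfunction_class\tphenotype_class\tviolated_rule\tmode\tinferred_via\n"
    )
    for f in findings:
        stream.write(
            f"{f.gene}\t{f.function_class}\t{f.phenotype_class}\t"
            f"{f.violated_rule}\t{f.mode}\t{f.inferred_via or ''}\n"
        )


def aggregate_by_pattern(
    findings: Iterable[InconsistencyFinding],
) -> dict[tuple[str, str], int]:
    """pattern (function, phenotype) -> number of distinct flagged genes."""
    genes: dict[tuple[str, str], set[str]] = {}
    for f in findings:
        genes.setdefault((f.function_class, f.phenotype_class), set()).add(f.gene)
    return {k: len(v) for k, v in sorted(genes.items())}
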