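"""Rule-based prediction of loss-of-function phenotypes from functions.

Each direct function annotation of a gene, combined with a matching
correspondence rule, yields a scored phenotype prediction: experimental
annotations predict at score 1.0, externally predicted functions pass their
confidence through.  Several licensing functions for the same phenotype
collapse to the best-scoring prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Sequence

from .annotations import AnnotationCorpus
from .ontology import OntologyGraph, descendants


@dataclass(frozen=True, order=True)
class PhenotypePrediction:
    gene: str
    phenotype_class: str
    score: float
    rule_kind: str
    source_function: str


def predict(
    functions: AnnotationCorpus,
    rules: Sequence,
    aspects: set[str] | None = frozenset({"P"}),
) -> list[PhenotypePrediction]:
    """Apply correspondence rules to direct function annotations.

    Only biological-process records (GAF aspect P) feed the rules by default
    — the rules are defined over processes; annotations without an aspect
    (e.g. predicted functions) always pass.  Pass ``aspects=None`` to widen.
    Per (gene, phenotype) duplicates keep the max score, ties broken
    deterministically.
    """
    by_function: dict[str, list] = {}
    for rule in rules:
        by_function.setdefault(rule.function_class, []).append(rule)

    best: dict[tuple[str, str], PhenotypePrediction] = {}
    for gene in sorted(functions.assignments):
        for ann in sorted(
            functions.assignments[gene],
            key=lambda a: (-a.score, a.class_id, a.evidence),
        ):
            if (
                aspects is not None
                and ann.aspect is not None
                and ann.aspect not in aspects
            ):
                continue
            for rule in by_function.get(ann.class_id, ()):
                key = (gene, rule.phenotype_class)
                cand = PhenotypePrediction(
                    gene=gene,
                    phenotype_class=rule.phenotype_class,
                    score=ann.score,
                    rule_kind=rule.rule_kind,
                    source_function=rule.function_class,
                )
                prev = best.get(key)
                if prev is None or cand.score > prev.score or (
                    cand.score == prev.score
                    and (cand.rule_kind, cand.source_function)
                    < (prev.rule_kind, prev.source_function)
                ):
                    best[key] = cand
    return sorted(best.values())


def split_novel(
    predictions: Sequence[PhenotypePrediction],
    existing: AnnotationCorpus,
    graph: OntologyGraph,
    match: str = "inferred",
) -> tuple[list[PhenotypePrediction], list[PhenotypePrediction]]:
    """Partition predictions into (found, novel) against asserted phenotypes.

    A prediction is *found* when the gene already has a phenotype annotation
    equal to the predicted class (``exact``), or additionally to any
    descendant of it (``inferred`` — an assertion to *increased B cell
    apoptosis* counts as a match for a predicted *increased apoptosis*).
    The partition is disjoint and exhaustive.
    """
    if match not in ("exact", "inferred"):
        raise ValueError(f"match must be exact|inferred, got {match!r}")
    found, novel = [], []
    for pred in predictions:
        asserted = existing.classes_of(pred.gene)
        if match == "exact" or pred.phenotype_class not in graph:
            hit = pred.phenotype_class in asserted
        else:
            hit = bool(descendants(graph, pred.phenotype_class) & asserted)
        (found if hit else novel).append(pred)
    return found, novel


def write_predictions_tsv(
    predictions: Iterable[PhenotypePrediction], stream: IO[str]
) -> None:
    stream.write("gene\tphenotype_class\tscore\trule_kind\tsource_function\n")
    for p in predictions:
        stream.write(
            f"{p.gene}\t{p.phenotype_class}\t{p.score:g}\t{p.rule_kind}\t"
            f"{p.source_function}\n"
        )


def predictions_as_corpus(
    predictions: Iterable[PhenotypePrediction],
) -> AnnotationCorpus:
    """View predictions as an annotation corpus (evidence ``RULE``)."""
    from .annotations import GeneAnnotation

    corpus = AnnotationCorpus()
    for p in predictions:
        corpus.add(
            p.gene,
            GeneAnnotation(class_id=p.phenotype_class, evidence="RULE", score=p.score),
        )
    return corpus
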