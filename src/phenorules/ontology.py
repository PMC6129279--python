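"""OBO ontology parsing and subsumption queries.

Loads GO-like and phenotype (MP/HPO-like) ontologies from OBO 1.2/1.4 flat
files into a queryable graph.  Beyond the plain ``is_a`` hierarchy the parser
retains each term's ``intersection_of`` tag group as a structured
:class:`LogicalDefinition` (genus + differentia), which is what the rule
engine consumes: GO regulation classes are defined as
``'biological regulation' and positively_regulates some P`` and phenotype
classes follow the Entity-Quality pattern over a GO process and a PATO
quality.

Only ``is_a`` participates in ancestor/descendant closure; closure is
reflexive (every class is its own ancestor and descendant).
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import networkx as nx

logger = logging.getLogger(__name__)

#: Relations the parser recognises out of the box.  Typedef stanzas in the
#: file extend this set; anything else is kept verbatim but flagged.
DEFAULT_RELATION_VOCABULARY = frozenset(
    {
        "part_of",
        "regulates",
        "positively_regulates",
        "negatively_regulates",
        "occurs_in",
        "has_part",
        "phenotype_of",
        "inheres_in",
        "has_quality",
        "has_modifier",
        "towards",
    }
)


class OboParseError(ValueError):
    """Malformed OBO input; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class OntologyError(ValueError):
    """Structural problem with the ontology graph (cycle, unknown class)."""


@dataclass(frozen=True)
class LogicalDefinition:
    """An ``intersection_of`` tag group: genus class plus differentia.

    ``differentia`` is an ordered tuple of ``(relation, filler)`` pairs, e.g.
    ``(("positively_regulates", "GO:0001783"),)`` for a positive-regulation
    class, or the Entity-Quality pair of a phenotype class.
    """

    defined_class: str
    genus: str | None
    differentia: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if self.genus is None and not self.differentia:
            raise ValueError(
                f"logical definition of {self.defined_class} has neither "
                "genus nor differentia"
            )


@dataclass
class OntologyGraph:
    """One or more merged ontologies: classes, is_a DAG, logical definitions.

    ``dag`` stores one edge per asserted ``is_a``, oriented child -> parent,
    so ``nx.descendants`` of a node walks *up* to its ancestors.
    """

    labels: dict[str, str] = field(default_factory=dict)
    dag: nx.DiGraph = field(default_factory=nx.DiGraph)
    relationships: list[tuple[str, str, str]] = field(default_factory=list)
    logical_definitions: dict[str, LogicalDefinition] = field(default_factory=dict)
    flagged_relations: set[str] = field(default_factory=set)
    n_obsolete_dropped: int = 0

    @property
    def classes(self) -> set[str]:
        return set(self.dag.nodes)

    @property
    def roots(self) -> set[str]:
        return {c for c in self.dag.nodes if self.dag.out_degree(c) == 0}

    def __contains__(self, class_id: str) -> bool:
        return self.dag.has_node(class_id)

    def __len__(self) -> int:
        return self.dag.number_of_nodes()

    def merged_with(self, other: "OntologyGraph") -> "OntologyGraph":
        """Union of two ontology graphs (disjoint or overlapping ids)."""
        g = OntologyGraph()
        g.labels = {**self.labels, **other.labels}
        g.dag = nx.compose(self.dag, other.dag)
        g.relationships = self.relationships + other.relationships
        g.logical_definitions = {
            **self.logical_definitions,
            **other.logical_definitions,
        }
        g.flagged_relations = self.flagged_relations | other.flagged_relations
        return g


def _parse_class_token(value: str) -> str:
    token = value.split("!")[0].strip()
    if ":" not in token or token.startswith(":") or token.endswith(":"):
        raise ValueError(f"not a CURIE: {value!r}")
    return token


def parse_obo(
    stream: Iterable[str] | IO[str],
    relation_vocabulary: Iterable[str] = DEFAULT_RELATION_VOCABULARY,
) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 text stream into an :class:`OntologyGraph`.

    Handles ``[Term]`` stanzas with ``id``, ``name``, ``is_a``,
    ``relationship``, ``intersection_of`` and ``is_obsolete`` tags, and
    ``[Typedef]`` stanzas (whose ids extend the relation vocabulary).
    Obsolete terms are dropped with a logged warning.  Raises
    :class:`OboParseError` on malformed lines (with line number) and on
    duplicate term ids; raises :class:`OntologyError` naming one cycle if the
    ``is_a`` graph is cyclic.
    """
    vocab = set(relation_vocabulary)
    terms: dict[str, dict] = {}
    order: list[str] = []

    stanza: str | None = None  # None = header
    current: dict | None = None

    def close_term() -> None:
        nonlocal current
        if current is None:
            return
        tid = current.get("id")
        if tid is None:
            raise OboParseError("[Term] stanza without id", current["_start"])
        if tid in terms:
            raise OboParseError(f"duplicate term id {tid}", current["_start"])
        terms[tid] = current
        order.append(tid)
        current = None

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        stripped = line.strip()
        if not stripped or stripped.startswith("!"):
            continue
        if stripped.startswith("[") and stripped.endswith("]"):
            close_term()
            stanza = stripped[1:-1]
            if stanza == "Term":
                current = {"_start": lineno, "is_a": [], "relationship": [],
                           "intersection_of": [], "obsolete": False}
            continue
        if ":" not in stripped:
            raise OboParseError(f"malformed line {stripped!r}", lineno)
        tag, _, value = stripped.partition(":")
        tag = tag.strip()
        value = value.strip()
        if stanza == "Typedef":
            if tag == "id":
                vocab.add(value.split("!")[0].strip())
            continue
        if stanza != "Term" or current is None:
            continue  # header or unknown stanza kind
        try:
            if tag == "id":
                current["id"] = _parse_class_token(value)
            elif tag == "name":
                current["name"] = value
            elif tag == "is_a":
                current["is_a"].append((_parse_class_token(value), lineno))
            elif tag == "relationship":
                parts = value.split("!")[0].split()
                if len(parts) != 2:
                    raise ValueError(f"expected 'relation target': {value!r}")
                current["relationship"].append((parts[0], _parse_class_token(parts[1]), lineno))
            elif tag == "intersection_of":
                parts = value.split("!")[0].split()
                if len(parts) == 1:
                    current["intersection_of"].append((None, _parse_class_token(parts[0])))
                elif len(parts) == 2:
                    current["intersection_of"].append((parts[0], _parse_class_token(parts[1])))
                else:
                    raise ValueError(f"bad intersection_of value: {value!r}")
            elif tag == "is_obsolete":
                current["obsolete"] = value.lower().startswith("true")
            # other tags (def, synonym, xref, ...) are ignored
        except OboParseError:
            raise
        except ValueError as exc:
            raise OboParseError(str(exc), lineno) from exc
    close_term()

    graph = OntologyGraph()
    live = {tid for tid in order if not terms[tid]["obsolete"]}
    n_obsolete = len(order) - len(live)
    if n_obsolete:
        logger.warning("dropped %d obsolete term(s)", n_obsolete)
    graph.n_obsolete_dropped = n_obsolete

    for tid in order:
        if tid not in live:
            continue
        graph.dag.add_node(tid)
        graph.labels[tid] = terms[tid].get("name", "")

    for tid in order:
        if tid not in live:
            continue
        term = terms[tid]
        for parent, lineno in term["is_a"]:
            if parent not in live:
                logger.warning(
                    "line %d: is_a target %s of %s is not a declared live "
                    "class; edge dropped", lineno, parent, tid)
                continue
            graph.dag.add_edge(tid, parent)
        for rel, target, lineno in term["relationship"]:
            if rel not in vocab:
                graph.flagged_relations.add(rel)
            if target in live:
                graph.relationships.append((rel, tid, target))
        genus: str | None = None
        differentia: list[tuple[str, str]] = []
        for rel, filler in term["intersection_of"]:
            if rel is None:
                if genus is None:
                    genus = filler
                else:
                    logger.warning(
                        "%s has multiple genus terms in intersection_of; "
                        "keeping %s", tid, genus)
            else:
                if rel not in vocab:
                    graph.flagged_relations.add(rel)
                differentia.append((rel, filler))
        if genus is not None or differentia:
            graph.logical_definitions[tid] = LogicalDefinition(
                defined_class=tid, genus=genus, differentia=tuple(differentia)
            )

    if not nx.is_directed_acyclic_graph(graph.dag):
        cycle = nx.find_cycle(graph.dag)
        path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[0][0]}"
        raise OntologyError(f"is_a hierarchy contains a cycle: {path}")
    return graph


def load_obo(
    path: str | Path,
    relation_vocabulary: Iterable[str] = DEFAULT_RELATION_VOCABULARY,
) -> OntologyGraph:
    """Load an OBO file from disk; ``.gz`` is handled transparently."""
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            return parse_obo(fh, relation_vocabulary)
    with open(path) as fh:
        return parse_obo(fh, relation_vocabulary)


def _require(graph: OntologyGraph, class_id: str) -> None:
    if class_id not in graph:
        raise OntologyError(f"unknown class {class_id}")


def ancestors(graph: OntologyGraph, class_id: str) -> set[str]:
    """Reflexive-transitive is_a ancestors of ``class_id`` (includes itself)."""
    _require(graph, class_id)
    # dag edges run child -> parent, so nx "descendants" are our ancestors
    return nx.descendants(graph.dag, class_id) | {class_id}


def descendants(graph: OntologyGraph, class_id: str) -> set[str]:
    """Reflexive-transitive is_a descendants of ``class_id`` (includes itself)."""
    _require(graph, class_id)
    return nx.ancestors(graph.dag, class_id) | {class_id}
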