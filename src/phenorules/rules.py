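"""Rule engine: EQ decomposition, regulation indexing, rule generation.

The biological hypothesis: a gene product annotated with *positive regulation
of P* should, upon loss of function, show a phenotype in which the rate of
*P* is decreased; symmetrically for negative regulation; and any gene product
involved in *P* should, upon loss of function, show an *abnormal P*
phenotype.  The three meta-rules and their mirrored inconsistency patterns
are generated by joining two indexes built from ontology logical definitions:

* regulation records — GO classes defined with a ``positively_regulates`` /
  ``negatively_regulates`` differentia over a target process;
* EQ decompositions — phenotype classes defined over a GO entity and a PATO
  quality, reduced to (entity, direction) with direction one of
  ``increased`` / ``decreased`` / ``abnormal``.

Rules pair regulators with the *opposite* direction (loss of an activator
lowers the rate), inconsistency patterns with the *same* direction.
Rule generation is strictly class-level: no propagation along the hierarchy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import yaml

from .ontology import OntologyGraph, ancestors

logger = logging.getLogger(__name__)

INCREASED = "increased"
DECREASED = "decreased"
ABNORMAL = "abnormal"

POSITIVE = "positive"
NEGATIVE = "negative"

#: rule kinds: function sign -> phenotype direction under loss of function
INC_DEC = "inc_dec"  # positive regulation -> decreased process
DEC_INC = "dec_inc"  # negative regulation -> increased process
ABN = "abnormal"     # involvement in P -> abnormal P

RULE_KINDS = (INC_DEC, DEC_INC, ABN)

_REGULATION_RELATIONS = {
    "positively_regulates": POSITIVE,
    "negatively_regulates": NEGATIVE,
}


@dataclass(frozen=True)
class QualityConfig:
    """PATO quality classes that determine a phenotype's direction.

    Defaults carry only the two universally used ids — increased rate
    (PATO:0000912) and abnormal (PATO:0000460); decreased-rate qualities are
    ontology-release-specific and must be declared by the caller or a config
    file.
    """

    increased_qualities: frozenset[str] = frozenset({"PATO:0000912"})
    decreased_qualities: frozenset[str] = frozenset()
    abnormal_qualities: frozenset[str] = frozenset({"PATO:0000460"})
    entity_prefixes: frozenset[str] = frozenset({"GO"})

    def __post_init__(self) -> None:
        inc, dec, abn = (
            self.increased_qualities,
            self.decreased_qualities,
            self.abnormal_qualities,
        )
        if inc & dec or inc & abn or dec & abn:
            raise ValueError("quality sets must be pairwise disjoint")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "QualityConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(
            increased_qualities=frozenset(data.get("increased_qualities", ["PATO:0000912"])),
            decreased_qualities=frozenset(data.get("decreased_qualities", [])),
            abnormal_qualities=frozenset(data.get("abnormal_qualities", ["PATO:0000460"])),
            entity_prefixes=frozenset(data.get("entity_prefixes", ["GO"])),
        )


@dataclass(frozen=True, order=True)
class EQDecomposition:
    """A phenotype class reduced to (GO entity, direction)."""

    phenotype_class: str
    entity: str
    direction: str  # increased | decreased | abnormal


@dataclass(frozen=True, order=True)
class RegulationRecord:
    """A class asserted (via logical definition) to regulate a process."""

    regulator: str
    regulated: str
    sign: str  # positive | negative


@dataclass(frozen=True, order=True)
class CorrespondenceRule:
    """function annotation -> predicted loss-of-function phenotype."""

    function_class: str
    phenotype_class: str
    rule_kind: str


@dataclass(frozen=True, order=True)
class InconsistencyPattern:
    """function/phenotype class pair whose co-annotation violates a rule."""

    function_class: str
    phenotype_class: str
    violated_rule: str


def decompose_phenotype_class(
    graph: OntologyGraph, class_id: str, quality_config: QualityConfig | None = None
) -> EQDecomposition | None:
    """Extract the (entity, direction) pair from a phenotype class definition.

    Returns a decomposition iff the class's logical definition references
    exactly one filler with a configured entity prefix (a GO process, by
    default) and qualities from exactly one direction.  An abnormal quality
    alongside an increased/decreased one acts as a modifier, not a direction.
    Returns ``None`` when the class has no such definition; logs a warning
    and returns ``None`` on ambiguous (both-direction) definitions.
    """
    q = quality_config or QualityConfig()
    ld = graph.logical_definitions.get(class_id)
    if ld is None:
        return None
    fillers = [filler for _, filler in ld.differentia]
    entities = [
        f for f in fillers if f.split(":", 1)[0] in q.entity_prefixes
    ]
    if len(entities) != 1:
        return None
    qualities = set(fillers)
    if ld.genus is not None:
        qualities.add(ld.genus)
    inc = qualities & q.increased_qualities
    dec = qualities & q.decreased_qualities
    abn = qualities & q.abnormal_qualities
    if inc and dec:
        logger.warning(
            "phenotype class %s has both increased and decreased qualities; "
            "skipping", class_id)
        return None
    if inc:
        direction = INCREASED
    elif dec:
        direction = DECREASED
    elif abn:
        direction = ABNORMAL
    else:
        return None
    return EQDecomposition(
        phenotype_class=class_id, entity=entities[0], direction=direction
    )


def decompose_all(
    graph: OntologyGraph, quality_config: QualityConfig | None = None
) -> list[EQDecomposition]:
    """Decompose every class in the graph; order sorted by class id."""
    out = []
    for class_id in sorted(graph.logical_definitions):
        dec = decompose_phenotype_class(graph, class_id, quality_config)
        if dec is not None:
            out.append(dec)
    return out


def index_regulations(
    graph: OntologyGraph,
    genus: str | None = None,
    use_relationship_fallback: bool = False,
) -> list[RegulationRecord]:
    """Collect regulation records from logical definitions.

    One record per ``positively_regulates`` / ``negatively_regulates``
    differentia.  ``genus`` optionally restricts to definitions whose genus
    is (a subclass of) the given class — the strict reading where regulation
    classes must be kinds of *biological regulation*.  With
    ``use_relationship_fallback`` plain relationship edges also contribute.
    """
    records: set[RegulationRecord] = set()

    def genus_ok(g: str | None) -> bool:
        if genus is None:
            return True
        if g is None or g not in graph:
            return False
        return genus in ancestors(graph, g)

    for class_id in sorted(graph.logical_definitions):
        ld = graph.logical_definitions[class_id]
        if not genus_ok(ld.genus):
            continue
        signs_seen = set()
        for rel, filler in ld.differentia:
            sign = _REGULATION_RELATIONS.get(rel)
            if sign is None:
                continue
            if class_id == filler:
                logger.warning("%s asserted to regulate itself; skipped", class_id)
                continue
            signs_seen.add(sign)
            records.add(RegulationRecord(class_id, filler, sign))
        if len(signs_seen) > 1:
            logger.warning(
                "%s carries both positive and negative regulation "
                "differentia; emitting both records", class_id)
    if use_relationship_fallback:
        for rel, src, tgt in graph.relationships:
            sign = _REGULATION_RELATIONS.get(rel)
            if sign is not None and src != tgt:
                records.add(RegulationRecord(src, tgt, sign))
    return sorted(records)


def build_correspondence_rules(
    regulations: Iterable[RegulationRecord],
    decompositions: Iterable[EQDecomposition],
) -> list[CorrespondenceRule]:
    """Join regulations with opposite-direction decompositions.

    positive regulation of P x (ph, P, decreased)  -> (regulator, ph, inc_dec)
    negative regulation of P x (ph, P, increased)  -> (regulator, ph, dec_inc)
    every (ph, P, abnormal)                        -> (P, ph, abnormal)

    Output is deduplicated and sorted by (function_class, phenotype_class).
    """
    by_entity: dict[tuple[str, str], list[EQDecomposition]] = {}
    rules: set[CorrespondenceRule] = set()
    for dec in decompositions:
        by_entity.setdefault((dec.entity, dec.direction), []).append(dec)
        if dec.direction == ABNORMAL:
            rules.add(CorrespondenceRule(dec.entity, dec.phenotype_class, ABN))
    for reg in regulations:
        wanted = DECREASED if reg.sign == POSITIVE else INCREASED
        kind = INC_DEC if reg.sign == POSITIVE else DEC_INC
        for dec in by_entity.get((reg.regulated, wanted), ()):
            rules.add(CorrespondenceRule(reg.regulator, dec.phenotype_class, kind))
    return sorted(rules)


def build_inconsistency_patterns(
    regulations: Iterable[RegulationRecord],
    decompositions: Iterable[EQDecomposition],
) -> list[InconsistencyPattern]:
    """Mirror join: same-direction pairs that would contradict the rules.

    positive regulation of P x (ph, P, increased) -> inc_dec violated
    negative regulation of P x (ph, P, decreased) -> dec_inc violated
    """
    by_entity: dict[tuple[str, str], list[EQDecomposition]] = {}
    for dec in decompositions:
        by_entity.setdefault((dec.entity, dec.direction), []).append(dec)
    patterns: set[InconsistencyPattern] = set()
    for reg in regulations:
        mirrored = INCREASED if reg.sign == POSITIVE else DECREASED
        kind = INC_DEC if reg.sign == POSITIVE else DEC_INC
        for dec in by_entity.get((reg.regulated, mirrored), ()):
            patterns.add(
                InconsistencyPattern(reg.regulator, dec.phenotype_class, kind)
            )
    return sorted(patterns)


# -- serialization -----------------------------------------------------------

_RULE_HEADER = "function_class\tphenotype_class\trule_kind"


def write_rules_tsv(rules: Sequence, stream: IO[str]) -> None:
    """Write rules or patterns as a 3-column TSV with header."""
    stream.write(_RULE_HEADER + "\n")
    for r in rules:
        kind = getattr(r, "rule_kind", None) or getattr(r, "violated_rule")
        stream.write(f"{r.function_class}\t{r.phenotype_class}\t{kind}\n")


def read_rules_tsv(stream: Iterable[str], as_patterns: bool = False) -> list:
    cls = InconsistencyPattern if as_patterns else CorrespondenceRule
    out = []
    for i, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("function_class"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"line {i}: expected 3 columns, got {len(parts)}")
        out.append(cls(parts[0], parts[1], parts[2]))
    return out
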