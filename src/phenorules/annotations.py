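"""Annotation I/O: GAF, phenotype TSV dialects, predicted functions, STRING.

Annotations live in an :class:`AnnotationCorpus` mapping genes to sets of
scored class assignments.  Experimental annotations carry score 1.0;
externally predicted functions keep their predictor's confidence in (0, 1].
``propagate`` applies the true-path rule (each ancestor inherits the maximum
score over its annotated descendants), after which the corpus is marked
``closed``.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Mapping

from .ontology import OntologyGraph, ancestors

logger = logging.getLogger(__name__)

#: GO evidence codes counted as experimental / curated.
EXPERIMENTAL_EVIDENCE = frozenset(
    {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "TAS", "IC"}
)


@dataclass(frozen=True)
class GeneAnnotation:
    class_id: str
    evidence: str = ""
    score: float = 1.0
    qualifiers: tuple[str, ...] = ()
    aspect: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.score <= 1.0):
            raise ValueError(f"score must be in (0, 1], got {self.score}")


@dataclass
class AnnotationCorpus:
    """gene -> set of annotations; ``closed`` marks ontology closure."""

    assignments: dict[str, set[GeneAnnotation]] = field(default_factory=dict)
    closed: bool = False

    @property
    def genes(self) -> set[str]:
        return set(self.assignments)

    def add(self, gene: str, ann: GeneAnnotation) -> None:
        self.assignments.setdefault(gene, set()).add(ann)

    def classes_of(self, gene: str, aspects: set[str] | None = None) -> set[str]:
        """Distinct class ids annotated to ``gene``.

        ``aspects`` restricts to annotations whose GAF aspect is in the set;
        annotations without an aspect (phenotypes, predictions) always pass.
        """
        out = set()
        for ann in self.assignments.get(gene, ()):
            if aspects is not None and ann.aspect is not None and ann.aspect not in aspects:
                continue
            out.add(ann.class_id)
        return out

    def n_annotations(self) -> int:
        return sum(len(s) for s in self.assignments.values())

    def merged_with(self, other: "AnnotationCorpus") -> "AnnotationCorpus":
        """Union of two corpora, keeping the max score per (gene, class)."""
        merged = AnnotationCorpus(closed=self.closed and other.closed)
        for corpus in (self, other):
            for gene, anns in corpus.assignments.items():
                for ann in anns:
                    merged.add(gene, ann)
        for gene, anns in merged.assignments.items():
            merged.assignments[gene] = _collapse_max(anns)
        return merged


def _collapse_max(anns: set[GeneAnnotation]) -> set[GeneAnnotation]:
    """Keep one annotation per class id — the max-score one, ties broken
    deterministically by (evidence, aspect)."""
    best: dict[str, GeneAnnotation] = {}
    for ann in sorted(anns, key=lambda a: (-a.score, a.evidence, a.aspect or "")):
        best.setdefault(ann.class_id, ann)
    return set(best.values())


def _open_text(source: str | Path | IO[str]) -> IO[str]:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    path = Path(source)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def parse_gaf(
    stream: Iterable[str] | str | Path,
    evidence_whitelist: frozenset[str] | set[str] = EXPERIMENTAL_EVIDENCE,
    drop_negated: bool = True,
    drop_contextual: bool = True,
) -> AnnotationCorpus:
    """Parse a GAF 2.x file, keeping filtered experimental annotations.

    Rows are kept iff the evidence code (col 7) is whitelisted; rows with a
    NOT qualifier (col 4) are dropped when ``drop_negated``; rows with a
    non-empty annotation extension (col 16) are dropped when
    ``drop_contextual`` (the machine-checkable reading of "context
    specific").  Gene key is the DB object id (col 2).
    """
    corpus = AnnotationCorpus()
    fh = _open_text(stream) if not _is_line_iter(stream) else stream
    for lineno, raw in enumerate(fh, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 15:
            raise ValueError(
                f"line {lineno}: GAF row has {len(cols)} columns, expected >= 15"
            )
        gene = cols[1]
        qualifiers = tuple(q for q in cols[3].split("|") if q)
        class_id = cols[4]
        evidence = cols[6]
        aspect = cols[8] or None
        extension = cols[15] if len(cols) > 15 else ""
        if evidence not in evidence_whitelist:
            continue
        if drop_negated and any(q == "NOT" or q.startswith("NOT|") for q in qualifiers):
            continue
        if drop_contextual and extension.strip():
            continue
        corpus.add(
            gene,
            GeneAnnotation(
                class_id=class_id,
                evidence=evidence,
                score=1.0,
                qualifiers=qualifiers,
                aspect=aspect,
            ),
        )
    return corpus


def _is_line_iter(obj) -> bool:
    return not isinstance(obj, (str, Path))


#: dialect -> (gene column, class column, expected class-id prefixes)
PHENOTYPE_DIALECTS: dict[str, tuple[int, int, frozenset[str] | None]] = {
    "simple": (0, 1, None),
    "mgi_gene_pheno": (6, 4, frozenset({"MP"})),
    "hpo_gene_pheno": (0, 3, frozenset({"HP"})),
}


def parse_phenotype_tsv(
    stream: Iterable[str] | str | Path,
    dialect: str = "simple",
    gene_col: int | None = None,
    class_col: int | None = None,
    expected_prefixes: set[str] | None = None,
) -> AnnotationCorpus:
    """Parse gene -> phenotype TSV files (MGI report / HPO / simple layouts).

    Column positions come from the dialect and may be overridden.  Class ids
    with an unexpected prefix are skipped with a warning; duplicates collapse
    to one annotation at score 1.0.
    """
    if dialect not in PHENOTYPE_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    d_gene, d_class, d_prefixes = PHENOTYPE_DIALECTS[dialect]
    gene_col = d_gene if gene_col is None else gene_col
    class_col = d_class if class_col is None else class_col
    prefixes = d_prefixes if expected_prefixes is None else frozenset(expected_prefixes)

    corpus = AnnotationCorpus()
    fh = stream if _is_line_iter(stream) else _open_text(stream)
    needed = max(gene_col, class_col) + 1
    for lineno, raw in enumerate(fh, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#") or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < needed:
            raise ValueError(
                f"line {lineno}: row has {len(cols)} columns, expected >= {needed}"
            )
        gene, class_id = cols[gene_col].strip(), cols[class_col].strip()
        prefix = class_id.split(":", 1)[0] if ":" in class_id else ""
        if not prefix or (prefixes is not None and prefix not in prefixes):
            logger.warning(
                "line %d: class id %r has unexpected prefix; skipped",
                lineno, class_id)
            continue
        corpus.add(gene, GeneAnnotation(class_id=class_id, evidence="", score=1.0))
    return corpus


def parse_predicted_functions(stream: Iterable[str] | str | Path) -> AnnotationCorpus:
    """Parse a (gene, GO class, score) TSV of externally predicted functions.

    Scores must lie in (0, 1]; annotations carry evidence code ``PRED``.
    """
    corpus = AnnotationCorpus()
    fh = stream if _is_line_iter(stream) else _open_text(stream)
    for lineno, raw in enumerate(fh, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise ValueError(f"line {lineno}: expected 3 columns, got {len(cols)}")
        try:
            score = float(cols[2])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: bad score {cols[2]!r}") from exc
        if not (0.0 < score <= 1.0):
            raise ValueError(f"line {lineno}: score {score} outside (0, 1]")
        corpus.add(
            cols[0], GeneAnnotation(class_id=cols[1], evidence="PRED", score=score)
        )
    return corpus


def map_ids(
    corpus: AnnotationCorpus,
    mapping: Mapping[str, str],
    on_missing: str = "drop",
) -> AnnotationCorpus:
    """Rename genes through an identifier mapping.

    ``on_missing``: ``drop`` removes unmapped genes (count logged), ``keep``
    passes them through unchanged, ``error`` raises.  Two source ids mapping
    onto one target merge their annotation sets.
    """
    if on_missing not in {"drop", "keep", "error"}:
        raise ValueError(f"on_missing must be drop|keep|error, got {on_missing!r}")
    out = AnnotationCorpus(closed=corpus.closed)
    dropped = 0
    for gene, anns in corpus.assignments.items():
        if gene in mapping:
            target = mapping[gene]
        elif on_missing == "keep":
            target = gene
        elif on_missing == "error":
            raise KeyError(f"gene {gene} has no identifier mapping")
        else:
            dropped += 1
            continue
        for ann in anns:
            out.add(target, ann)
    if dropped:
        logger.info("map_ids: dropped %d unmapped gene(s)", dropped)
    for gene in out.assignments:
        out.assignments[gene] = _collapse_max(out.assignments[gene])
    return out


def propagate(corpus: AnnotationCorpus, graph: OntologyGraph) -> AnnotationCorpus:
    """Close the corpus over is_a: ancestors get the max descendant score.

    Annotations to classes absent from the graph are kept as-is (warned
    once).  Idempotent; never increases any score.
    """
    out = AnnotationCorpus(closed=True)
    missing: set[str] = set()
    for gene, anns in corpus.assignments.items():
        pool: set[GeneAnnotation] = set()
        for ann in anns:
            if ann.class_id not in graph:
                missing.add(ann.class_id)
                pool.add(ann)
                continue
            for anc in ancestors(graph, ann.class_id):
                pool.add(replace(ann, class_id=anc))
        out.assignments[gene] = _collapse_max(pool)
    if missing:
        logger.warning(
            "propagate: %d annotated class(es) not in ontology; kept "
            "unpropagated", len(missing))
    return out


def parse_string_links(
    stream: Iterable[str] | str | Path,
    min_score: int = 300,
    id_map: Mapping[str, str] | None = None,
) -> set[tuple[str, str]]:
    """Parse STRING protein.links rows, keeping confidence >= ``min_score``.

    Rows are whitespace-separated ``protein1 protein2 combined_score``; a
    non-numeric header row is skipped.  With ``id_map`` both endpoints must
    map or the row is dropped.  Self-pairs are removed and pairs are
    canonicalized as (min, max) by string order.
    """
    pairs: set[tuple[str, str]] = set()
    fh = stream if _is_line_iter(stream) else _open_text(stream)
    for lineno, raw in enumerate(fh, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"line {lineno}: expected 3 fields, got {len(parts)}")
        try:
            score = int(float(parts[2]))
        except ValueError:
            if lineno == 1:
                continue  # header
            raise ValueError(f"line {lineno}: bad score {parts[2]!r}")
        if score < min_score:
            continue
        a, b = parts[0], parts[1]
        if id_map is not None:
            if a not in id_map or b not in id_map:
                continue
            a, b = id_map[a], id_map[b]
        if a == b:
            continue
        pairs.add((min(a, b), max(a, b)))
    return pairs
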