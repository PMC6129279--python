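"""Information content, Resnik similarity, and BMA gene-gene similarity.

IC of a class is ``-ln p(c)`` where ``p(c)`` is the fraction of annotated
genes carrying the class after ontology closure (so the annotated root has
IC 0).  Resnik similarity of two classes is the IC of their most informative
common ancestor (MICA).  Gene-gene similarity combines pairwise Resnik
values over the genes' direct phenotype sets with the Best-Match-Average
strategy:

    sim(A, B) = ( avg_{a in A} max_{b in B} s(a, b)
                + avg_{b in B} max_{a in A} s(a, b) ) / 2

Normalized matrices divide by the global maximum entry, giving scores in
[0, 1] usable directly as interaction-prediction confidences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np

from .annotations import AnnotationCorpus, propagate
from .ontology import OntologyGraph, ancestors


@dataclass
class ICTable:
    """Class -> information content, over a gene-annotation corpus."""

    ic: dict[str, float]
    corpus_size: int
    basis: str = "genes"

    def __contains__(self, class_id: str) -> bool:
        return class_id in self.ic

    def __getitem__(self, class_id: str) -> float:
        return self.ic[class_id]


@dataclass
class SimilarityMatrix:
    genes: list[str]
    values: np.ndarray  # symmetric, >= 0
    normalized: bool

    def pair_scores(self) -> dict[tuple[str, str], float]:
        """Long-format off-diagonal scores keyed by canonical (min,max) pair."""
        out: dict[tuple[str, str], float] = {}
        for i, gi in enumerate(self.genes):
            for j in range(i + 1, len(self.genes)):
                gj = self.genes[j]
                out[(min(gi, gj), max(gi, gj))] = float(self.values[i, j])
        return out

    def write_tsv(self, stream: IO[str]) -> None:
        stream.write("gene_a\tgene_b\tscore\n")
        for (a, b), s in sorted(self.pair_scores().items()):
            stream.write(f"{a}\t{b}\t{s:.6g}\n")


def information_content(
    phenotypes: AnnotationCorpus, graph: OntologyGraph
) -> ICTable:
    """IC(c) = -ln( genes annotated to c after closure / annotated genes ).

    Classes never annotated are absent from the table.  Raises on an empty
    corpus.
    """
    if not phenotypes.genes:
        raise ValueError("cannot compute information content of an empty corpus")
    closed = phenotypes if phenotypes.closed else propagate(phenotypes, graph)
    counts: dict[str, int] = {}
    n_genes = 0
    for gene in closed.assignments:
        classes = closed.classes_of(gene)
        if not classes:
            continue
        n_genes += 1
        for c in classes:
            counts[c] = counts.get(c, 0) + 1
    if n_genes == 0:
        raise ValueError("corpus has no annotated genes")
    table = {c: -math.log(k / n_genes) for c, k in counts.items()}
    return ICTable(ic=table, corpus_size=n_genes)


def resnik(
    c1: str, c2: str, ic: ICTable, graph: OntologyGraph
) -> float:
    """IC of the most informative common ancestor; 0 if none carries IC."""
    common = ancestors(graph, c1) & ancestors(graph, c2)
    return max((ic[c] for c in common if c in ic), default=0.0)


def bma(
    set_a: Iterable[str],
    set_b: Iterable[str],
    ic: ICTable,
    graph: OntologyGraph,
) -> float:
    """Best-Match-Average combination of pairwise Resnik similarities."""
    a, b = sorted(set(set_a)), sorted(set(set_b))
    if not a or not b:
        raise ValueError("bma requires two non-empty class sets")
    sim = [[resnik(x, y, ic, graph) for y in b] for x in a]
    row = sum(max(r) for r in sim) / len(a)
    col = sum(max(sim[i][j] for i in range(len(a))) for j in range(len(b))) / len(b)
    return (row + col) / 2.0


class _ResnikCache:
    """Memoized Resnik over precomputed ancestor IC maps."""

    def __init__(self, ic: ICTable, graph: OntologyGraph):
        self.ic = ic
        self.graph = graph
        self._anc: dict[str, dict[str, float]] = {}
        self._pair: dict[tuple[str, str], float] = {}

    def _anc_ic(self, c: str) -> dict[str, float]:
        got = self._anc.get(c)
        if got is None:
            got = {a: self.ic[a] for a in ancestors(self.graph, c) if a in self.ic}
            self._anc[c] = got
        return got

    def __call__(self, c1: str, c2: str) -> float:
        key = (c1, c2) if c1 <= c2 else (c2, c1)
        got = self._pair.get(key)
        if got is None:
            a1, a2 = self._anc_ic(c1), self._anc_ic(c2)
            if len(a2) < len(a1):
                a1, a2 = a2, a1
            got = max((v for c, v in a1.items() if c in a2), default=0.0)
            self._pair[key] = got
        return got


def gene_similarity_matrix(
    phenotypes: AnnotationCorpus,
    ic: ICTable,
    graph: OntologyGraph,
    normalize: bool = True,
) -> SimilarityMatrix:
    """Pairwise BMA similarity over genes' direct phenotype class sets.

    Genes whose direct classes are all absent from the graph are excluded.
    With ``normalize`` all entries (diagonal included) are divided by the
    global maximum, so the matrix maximum is exactly 1 whenever any nonzero
    similarity exists.
    """
    sets: dict[str, list[str]] = {}
    for gene in sorted(phenotypes.assignments):
        classes = sorted(c for c in phenotypes.classes_of(gene) if c in graph)
        if classes:
            sets[gene] = classes
    genes = sorted(sets)
    n = len(genes)
    values = np.zeros((n, n))
    s = _ResnikCache(ic, graph)

    def _bma(a: list[str], b: list[str]) -> float:
        sim = [[s(x, y) for y in b] for x in a]
        row = sum(max(r) for r in sim) / len(a)
        col = sum(max(sim[i][j] for i in range(len(a))) for j in range(len(b))) / len(b)
        return (row + col) / 2.0

    for i in range(n):
        for j in range(i, n):
            v = _bma(sets[genes[i]], sets[genes[j]])
            values[i, j] = values[j, i] = v
    if normalize:
        m = values.max() if n else 0.0
        if m > 0:
            values = values / m
    return SimilarityMatrix(genes=genes, values=values, normalized=normalize)


def write_ic_tsv(ic: ICTable, stream: IO[str]) -> None:
    stream.write("class_id\tic\n")
    for c in sorted(ic.ic):
        stream.write(f"{c}\t{ic.ic[c]:.6g}\n")
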