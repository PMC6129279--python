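"""Evaluation metrics: Fmax over an ontology, and ROC AUC for ranked pairs.

Fmax is the protein-function-prediction metric popularised by the CAFA
challenges, here applied to phenotype predictions.  For a threshold ``t``,
each gene's predicted set ``P_i(t)`` is the ontology closure of its
predictions scoring at least ``t``; ``T_i`` is the closure of its asserted
annotations.  Per-gene precision and recall are

    pr_i(t) = |P_i(t) & T_i| / |P_i(t)|        (defined when P_i(t) nonempty)
    rc_i(t) = |P_i(t) & T_i| / |T_i|

Precision is averaged over the m(t) genes with at least one prediction at
``t``; recall over all n genes in the evaluation set (genes with at least
one asserted annotation and at least one prediction at any threshold).
Fmax is the maximum over the threshold grid of the harmonic mean of the two
averages.  Ontology roots are excluded from both sets (closure predicts
them trivially).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from sklearn.metrics import roc_auc_score

from .annotations import AnnotationCorpus, propagate
from .ontology import OntologyGraph, ancestors
from .predictor import PhenotypePrediction

#: CAFA-style default grid: 0.00, 0.01, ..., 1.00
DEFAULT_GRID = tuple(round(i / 100, 2) for i in range(101))


@dataclass
class FmaxResult:
    fmax: float
    best_threshold: float
    curve: list[tuple[float, float, float, int]]  # (t, AvgPr, AvgRc, m)
    n: int


@dataclass
class RocResult:
    auc: float
    positives: int
    negatives: int


def fmax(
    predictions: Sequence[PhenotypePrediction],
    truth: AnnotationCorpus,
    graph: OntologyGraph,
    grid: Sequence[float] = DEFAULT_GRID,
    propagate_predictions: bool = True,
) -> FmaxResult:
    """Compute Fmax of scored predictions against asserted annotations.

    ``truth`` is closed over the ontology if not already; predicted sets are
    likewise closure-propagated per threshold unless
    ``propagate_predictions`` is false.  Raises on an empty evaluation set.
    """
    roots = graph.roots
    closed_truth = truth if truth.closed else propagate(truth, graph)

    truth_sets: dict[str, frozenset[str]] = {}
    for gene in closed_truth.assignments:
        t = frozenset(closed_truth.classes_of(gene)) - roots
        if t:
            truth_sets[gene] = t

    preds_by_gene: dict[str, list[PhenotypePrediction]] = {}
    for p in predictions:
        preds_by_gene.setdefault(p.gene, []).append(p)

    eval_genes = sorted(set(truth_sets) & set(preds_by_gene))
    n = len(eval_genes)
    if n == 0:
        raise ValueError("empty evaluation set: no gene has both truth and predictions")

    closure_cache: dict[str, frozenset[str]] = {}

    def closure(c: str) -> frozenset[str]:
        got = closure_cache.get(c)
        if got is None:
            got = frozenset(ancestors(graph, c)) if c in graph else frozenset({c})
            closure_cache[c] = got
        return got

    # per gene, a cache from the frozen at-threshold class set to its closure
    set_cache: dict[frozenset[str], frozenset[str]] = {}

    def predicted_set(gene: str, t: float) -> frozenset[str]:
        raw = frozenset(
            p.phenotype_class for p in preds_by_gene[gene] if p.score >= t
        )
        if not propagate_predictions:
            return raw - roots
        got = set_cache.get(raw)
        if got is None:
            full: set[str] = set()
            for c in raw:
                full |= closure(c)
            got = frozenset(full) - roots
            set_cache[raw] = got
        return got

    best_f, best_t = 0.0, float(grid[0])
    curve: list[tuple[float, float, float, int]] = []
    for t in grid:
        m = 0
        pr_sum = 0.0
        rc_sum = 0.0
        for gene in eval_genes:
            pset = predicted_set(gene, t)
            tset = truth_sets[gene]
            hits = len(pset & tset)
            if pset:
                m += 1
                pr_sum += hits / len(pset)
            rc_sum += hits / len(tset)
        avg_pr = pr_sum / m if m else 0.0
        avg_rc = rc_sum / n
        f = (
            2 * avg_pr * avg_rc / (avg_pr + avg_rc)
            if (avg_pr + avg_rc) > 0
            else 0.0
        )
        curve.append((float(t), avg_pr, avg_rc, m))
        if f > best_f:
            best_f, best_t = f, float(t)
    return FmaxResult(fmax=best_f, best_threshold=best_t, curve=curve, n=n)


def roc_auc(
    pair_scores: Mapping[tuple[str, str], float],
    positives: Iterable[tuple[str, str]],
) -> RocResult:
    """AUC of similarity-ranked gene pairs against known interactions.

    Pairs are canonicalized as (min, max).  Every positive must be scored;
    negatives are the remaining scored pairs.  Ties are handled by the
    midrank (Mann-Whitney) convention.
    """
    def canon(pair: tuple[str, str]) -> tuple[str, str]:
        a, b = pair
        return (a, b) if a <= b else (b, a)

    scores = {canon(p): s for p, s in pair_scores.items()}
    pos = {canon(p) for p in positives}
    missing = pos - set(scores)
    if missing:
        raise ValueError(
            f"{len(missing)} positive pair(s) have no similarity score, "
            f"e.g. {sorted(missing)[0]}"
        )
    items = sorted(scores.items())
    y = [1 if pair in pos else 0 for pair, _ in items]
    n_pos = sum(y)
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative pair")
    auc = float(roc_auc_score(y, [s for _, s in items]))
    return RocResult(auc=auc, positives=n_pos, negatives=n_neg)
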