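"""Synthetic toy ontologies, annotation corpora, and interaction networks.

Everything downstream — rule generation, consistency checking, prediction,
similarity, evaluation — is testable against these self-contained fixtures,
which emulate the real inputs at desk scale:

* a GO-like process ontology: a random is_a DAG of biological processes plus
  regulator classes carrying ``positively_regulates`` /
  ``negatively_regulates`` logical definitions over sampled targets;
* a phenotype ontology with Entity-Quality logical definitions: for each
  covered process an *abnormal*, *increased* and *decreased* phenotype
  class, mirroring the process hierarchy on the abnormal layer and declaring
  the PATO quality classes it uses;
* annotation corpora where each gene's phenotypes follow the rules applied
  to its functions, except for a planted fraction of rule-violating pairs
  and optional random phenotype noise;
* an interaction network whose positive pairs are drawn preferentially
  among genes sharing phenotype classes (tunable signal strength).

Every planted regulation axiom, EQ definition, and (in)consistent pair is
recorded in a plant log, the oracle against which the test suite asserts.
Identical spec + seed yields byte-identical serialized fixtures.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .annotations import AnnotationCorpus, GeneAnnotation
from .ontology import OntologyGraph, parse_obo
from .rules import (
    ABN,
    ABNORMAL,
    DEC_INC,
    DECREASED,
    INC_DEC,
    INCREASED,
    NEGATIVE,
    POSITIVE,
    CorrespondenceRule,
    InconsistencyPattern,
    QualityConfig,
)

GO_ROOT = "GO:0000001"
GO_REGULATION = "GO:0000002"
MP_ROOT = "MP:0000001"
PATO_ROOT = "PATO:0000001"
PATO_INCREASED = "PATO:0000912"
PATO_DECREASED = "PATO:0000911"
PATO_ABNORMAL = "PATO:0000460"


def default_quality_config() -> QualityConfig:
    """Quality table matching the fixture ontologies."""
    return QualityConfig(
        increased_qualities=frozenset({PATO_INCREASED}),
        decreased_qualities=frozenset({PATO_DECREASED}),
        abnormal_qualities=frozenset({PATO_ABNORMAL}),
        entity_prefixes=frozenset({"GO"}),
    )


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic dataset.

    Defaults match the scale used throughout the test suite: 50 processes,
    20 positive and 20 negative regulators, full EQ coverage, 100 genes,
    10% phenotype noise and 10% of genes given a planted rule-violating
    pair.
    """

    n_processes: int = 50
    n_regulators_pos: int = 20
    n_regulators_neg: int = 20
    eq_coverage: float = 1.0
    n_genes: int = 100
    annotation_noise: float = 0.1
    inconsistency_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("eq_coverage", "annotation_noise", "inconsistency_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_processes", "n_regulators_pos", "n_regulators_neg", "n_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_regulators_pos > self.n_processes or (
            self.n_regulators_neg > self.n_processes
        ):
            raise ValueError(
                "regulator counts must not exceed n_processes (each regulator "
                "gets a distinct target so pattern pairs stay unambiguous)"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FixtureSpec":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _process_id(i: int) -> str:
    return f"GO:{10 + i:07d}"


def _regulator_id(sign: str, i: int) -> str:
    base = 5000000 if sign == POSITIVE else 6000000
    return f"GO:{base + i:07d}"


def _pheno_id(kind: str, i: int) -> str:
    base = {ABNORMAL: 1000000, INCREASED: 2000000, DECREASED: 3000000}[kind]
    return f"MP:{base + i:07d}"


def make_toy_obo_texts(spec: FixtureSpec) -> tuple[str, str, dict]:
    """Serialize the GO-like and phenotype-like fixture ontologies as OBO.

    Returns (go_text, pheno_text, plant_log); the plant log records every
    regulation axiom and EQ definition written.
    """
    rng = random.Random(spec.seed)
    processes = [_process_id(i) for i in range(spec.n_processes)]

    go = ["format-version: 1.2", ""]
    for rel in ("positively_regulates", "negatively_regulates"):
        go += ["[Typedef]", f"id: {rel}", f"name: {rel}", ""]
    go += ["[Term]", f"id: {GO_ROOT}", "name: biological process", ""]
    go += ["[Term]", f"id: {GO_REGULATION}", "name: biological regulation",
           f"is_a: {GO_ROOT}", ""]

    parents_of: dict[str, list[str]] = {}
    for i, proc in enumerate(processes):
        pool = [GO_ROOT] + processes[:i]
        k = 1 if len(pool) == 1 else rng.choice((1, 1, 2))
        parents = sorted(rng.sample(pool, k))
        parents_of[proc] = parents
        go += ["[Term]", f"id: {proc}", f"name: process {i}"]
        go += [f"is_a: {p}" for p in parents]
        go += [""]

    regulations: list[tuple[str, str, str]] = []
    for sign, count in ((POSITIVE, spec.n_regulators_pos),
                        (NEGATIVE, spec.n_regulators_neg)):
        targets = rng.sample(processes, count) if count else []
        rel = "positively_regulates" if sign == POSITIVE else "negatively_regulates"
        word = "positive" if sign == POSITIVE else "negative"
        for i, target in enumerate(targets):
            reg = _regulator_id(sign, i)
            regulations.append((reg, target, sign))
            go += ["[Term]", f"id: {reg}",
                   f"name: {word} regulation of process (target {target})",
                   f"is_a: {GO_REGULATION}",
                   f"intersection_of: {GO_REGULATION}",
                   f"intersection_of: {rel} {target}", ""]

    pheno = ["format-version: 1.2", ""]
    for rel in ("phenotype_of", "has_quality"):
        pheno += ["[Typedef]", f"id: {rel}", f"name: {rel}", ""]
    pheno += ["[Term]", f"id: {MP_ROOT}", "name: phenotype", ""]
    pheno += ["[Term]", f"id: {PATO_ROOT}", "name: quality", ""]
    for pato, name in ((PATO_INCREASED, "increased rate"),
                       (PATO_DECREASED, "decreased rate"),
                       (PATO_ABNORMAL, "abnormal")):
        pheno += ["[Term]", f"id: {pato}", f"name: {name}",
                  f"is_a: {PATO_ROOT}", ""]

    n_covered = round(spec.eq_coverage * spec.n_processes)
    covered = sorted(rng.sample(range(spec.n_processes), n_covered))
    covered_set = set(covered)
    eq_plants: list[tuple[str, str, str]] = []
    for i in covered:
        proc = processes[i]
        abn_id = _pheno_id(ABNORMAL, i)
        # abnormal layer mirrors the process DAG where coverage allows
        abn_parents = sorted(
            _pheno_id(ABNORMAL, processes.index(p))
            for p in parents_of[proc]
            if p != GO_ROOT and processes.index(p) in covered_set
        ) or [MP_ROOT]
        pheno += ["[Term]", f"id: {abn_id}", f"name: abnormal process {i}"]
        pheno += [f"is_a: {p}" for p in abn_parents]
        pheno += [f"intersection_of: {MP_ROOT}",
                  f"intersection_of: phenotype_of {proc}",
                  f"intersection_of: has_quality {PATO_ABNORMAL}", ""]
        eq_plants.append((abn_id, proc, ABNORMAL))
        for kind, pato in ((INCREASED, PATO_INCREASED), (DECREASED, PATO_DECREASED)):
            cid = _pheno_id(kind, i)
            pheno += ["[Term]", f"id: {cid}", f"name: {kind} process {i}",
                      f"is_a: {abn_id}",
                      f"intersection_of: {MP_ROOT}",
                      f"intersection_of: phenotype_of {proc}",
                      f"intersection_of: has_quality {pato}",
                      f"intersection_of: has_quality {PATO_ABNORMAL}", ""]
            eq_plants.append((cid, proc, kind))

    plant_log = {
        "regulations": [list(r) for r in regulations],
        "eq": [list(e) for e in eq_plants],
        "processes": processes,
    }
    return "\n".join(go) + "\n", "\n".join(pheno) + "\n", plant_log


def make_toy_ontologies(
    spec: FixtureSpec,
) -> tuple[OntologyGraph, OntologyGraph, dict]:
    """Build and parse the fixture ontologies; see :func:`make_toy_obo_texts`."""
    go_text, pheno_text, plant_log = make_toy_obo_texts(spec)
    go = parse_obo(go_text.splitlines())
    pheno = parse_obo(pheno_text.splitlines())
    return go, pheno, plant_log


def make_annotation_corpora(
    spec: FixtureSpec,
    go: OntologyGraph,
    pheno: OntologyGraph,
    rules: Sequence[CorrespondenceRule],
    patterns: Sequence[InconsistencyPattern],
) -> tuple[AnnotationCorpus, AnnotationCorpus, dict]:
    """Generate function and phenotype corpora with planted structure.

    Each gene draws 1-3 correspondence rules; its function annotations are
    the rules' function classes and its phenotype annotations the rules'
    phenotype classes (rule-consistent by construction).  A gene never draws
    an inc_dec and a dec_inc rule over the same regulated process — the two
    would jointly realize a genuine inconsistency pattern and blur the plant
    log.  A planted ``inconsistency_rate`` fraction of genes additionally
    receives one mirror-pattern (function, phenotype) pair;
    ``annotation_noise`` adds a random phenotype class per affected gene.

    Returns (functions, phenotypes, truth_log) where the truth log maps
    genes to their planted consistent pairs, inconsistent pair (if any) and
    noise classes.
    """
    rng = random.Random(spec.seed + 1)
    rules = sorted(rules)
    patterns = sorted(patterns)
    if not rules:
        raise ValueError("cannot generate corpora without correspondence rules")

    # regulated process underlying each rule's phenotype, for conflict checks
    entity_of_phenotype: dict[str, str] = {}
    for class_id, ld in pheno.logical_definitions.items():
        for _, filler in ld.differentia:
            if filler.startswith("GO:"):
                entity_of_phenotype[class_id] = filler

    functions = AnnotationCorpus()
    phenotypes = AnnotationCorpus()
    truth_log: dict[str, dict] = {}
    pheno_universe = sorted(c for c in pheno.classes if c.startswith("MP:") and c != MP_ROOT)

    for g in range(spec.n_genes):
        gene = f"g{g + 1:04d}"
        log = {"consistent": [], "inconsistent": None, "noise": []}
        k = rng.randint(1, 3)
        chosen: list[CorrespondenceRule] = []
        used_signed_entities: set[tuple[str, str]] = set()
        attempts = 0
        while len(chosen) < k and attempts < 50:
            attempts += 1
            rule = rng.choice(rules)
            entity = entity_of_phenotype.get(rule.phenotype_class, rule.phenotype_class)
            if rule.rule_kind == INC_DEC and (entity, DEC_INC) in used_signed_entities:
                continue
            if rule.rule_kind == DEC_INC and (entity, INC_DEC) in used_signed_entities:
                continue
            if rule in chosen:
                continue
            used_signed_entities.add((entity, rule.rule_kind))
            chosen.append(rule)
        for rule in chosen:
            functions.add(gene, GeneAnnotation(
                class_id=rule.function_class, evidence="IMP", score=1.0, aspect="P"))
            phenotypes.add(gene, GeneAnnotation(class_id=rule.phenotype_class))
            log["consistent"].append(
                [rule.function_class, rule.phenotype_class, rule.rule_kind])
        if patterns and rng.random() < spec.inconsistency_rate:
            pat = rng.choice(patterns)
            functions.add(gene, GeneAnnotation(
                class_id=pat.function_class, evidence="IMP", score=1.0, aspect="P"))
            phenotypes.add(gene, GeneAnnotation(class_id=pat.phenotype_class))
            log["inconsistent"] = [
                pat.function_class, pat.phenotype_class, pat.violated_rule]
        if pheno_universe and rng.random() < spec.annotation_noise:
            noise_class = rng.choice(pheno_universe)
            phenotypes.add(gene, GeneAnnotation(class_id=noise_class))
            log["noise"].append(noise_class)
        truth_log[gene] = log
    return functions, phenotypes, truth_log


def make_interaction_network(
    spec: FixtureSpec,
    phenotypes: AnnotationCorpus,
    signal: float = 1.0,
    n_positives: int | None = None,
    seed: int | None = None,
) -> tuple[set[tuple[str, str]], list[tuple[str, str]]]:
    """Sample interaction positives among phenotype-sharing gene pairs.

    ``signal`` in [0, 1] is the probability that each positive is drawn from
    the pairs sharing at least one direct phenotype class rather than
    uniformly from all pairs; 0 yields a pure null network.  Returns
    (positives, all candidate pairs); negatives are the complement.
    """
    if not phenotypes.genes:
        raise ValueError("cannot build an interaction network from an empty corpus")
    if not (0.0 <= signal <= 1.0):
        raise ValueError(f"signal must be in [0, 1], got {signal}")
    rng = random.Random(spec.seed + 2 if seed is None else seed)
    genes = sorted(phenotypes.genes)
    sets = {g: phenotypes.classes_of(g) for g in genes}
    all_pairs = [
        (genes[i], genes[j])
        for i in range(len(genes))
        for j in range(i + 1, len(genes))
    ]
    sharing = [p for p in all_pairs if sets[p[0]] & sets[p[1]]]
    if n_positives is None:
        n_positives = max(1, len(genes))
    n_positives = min(n_positives, len(all_pairs))
    want_share = sum(1 for _ in range(n_positives) if rng.random() < signal)
    want_share = min(want_share, len(sharing))
    positives: set[tuple[str, str]] = set(rng.sample(sharing, want_share))
    if len(positives) < n_positives:
        remaining = [p for p in all_pairs if p not in positives]
        positives |= set(
            rng.sample(remaining, n_positives - len(positives)))
    return positives, all_pairs


# -- file emission for the CLI ----------------------------------------------

def write_fixture_files(spec: FixtureSpec, outdir: str | Path) -> dict:
    """Write OBO / GAF / TSV / links / plant-log fixture files to ``outdir``."""
    from .rules import (
        build_correspondence_rules,
        build_inconsistency_patterns,
        decompose_all,
        index_regulations,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    go_text, pheno_text, plant_log = make_toy_obo_texts(spec)
    (outdir / "go_fixture.obo").write_text(go_text)
    (outdir / "pheno_fixture.obo").write_text(pheno_text)

    go = parse_obo(go_text.splitlines())
    pheno = parse_obo(pheno_text.splitlines())
    qc = default_quality_config()
    rules = build_correspondence_rules(
        index_regulations(go), decompose_all(pheno, qc))
    patterns = build_inconsistency_patterns(
        index_regulations(go), decompose_all(pheno, qc))
    functions, phenotypes, truth_log = make_annotation_corpora(
        spec, go, pheno, rules, patterns)

    with open(outdir / "functions.gaf", "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for gene in sorted(functions.assignments):
            for ann in sorted(functions.assignments[gene],
                              key=lambda a: a.class_id):
                fh.write(
                    "FIX\t{g}\t{g}\t\t{c}\tFIX:0000001\t{e}\t\tP\t\t\t"
                    "protein\ttaxon:0\t20180101\tFIX\t\t\n".format(
                        g=gene, c=ann.class_id, e=ann.evidence or "IMP"))
    with open(outdir / "phenotypes.tsv", "w") as fh:
        for gene in sorted(phenotypes.assignments):
            for c in sorted(phenotypes.classes_of(gene)):
                fh.write(f"{gene}\t{c}\n")

    positives, all_pairs = make_interaction_network(spec, phenotypes)
    with open(outdir / "links.tsv", "w") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for a, b in sorted(all_pairs):
            score = 700 if (a, b) in positives else 150
            fh.write(f"{a} {b} {score}\n")

    with open(outdir / "quality_config.yaml", "w") as fh:
        qc = default_quality_config()
        yaml.safe_dump(
            {
                "increased_qualities": sorted(qc.increased_qualities),
                "decreased_qualities": sorted(qc.decreased_qualities),
                "abnormal_qualities": sorted(qc.abnormal_qualities),
                "entity_prefixes": sorted(qc.entity_prefixes),
            },
            fh,
        )
    with open(outdir / "plant_log.json", "w") as fh:
        json.dump(
            {"spec": asdict(spec), "ontologies": plant_log, "corpora": truth_log,
             "positives": sorted(map(list, positives))},
            fh, indent=1, sort_keys=True)
    return plant_log
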