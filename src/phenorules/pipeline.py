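"""End-to-end orchestration: rules -> check -> predict -> sim -> eval.

``run_pipeline`` executes the whole workflow from a :class:`RunConfig`,
writing plain-text outputs under a fixed directory layout (``rules/``,
``findings/``, ``predictions/``, ``sim/``, ``eval/``) plus a machine-
readable manifest with input checksums and per-stage row counts.  Stage
outputs are pure functions of the declared inputs, so reruns on identical
inputs yield identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotations import (
    AnnotationCorpus,
    parse_gaf,
    parse_phenotype_tsv,
    parse_predicted_functions,
    parse_string_links,
)
from .consistency import check_corpus, write_findings_tsv
from .evaluation import fmax, roc_auc
from .ontology import load_obo
from .predictor import (
    predict,
    predictions_as_corpus,
    split_novel,
    write_predictions_tsv,
)
from .rules import (
    QualityConfig,
    build_correspondence_rules,
    build_inconsistency_patterns,
    decompose_all,
    index_regulations,
    write_rules_tsv,
)
from .similarity import gene_similarity_matrix, information_content, write_ic_tsv

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    go_obo: str
    pheno_obo: str
    gaf: str
    phenotype_tsv: str
    outdir: str
    phenotype_dialect: str = "simple"
    quality_config: str | None = None
    predicted_functions: str | None = None
    string_links: str | None = None
    min_string_score: int = 300
    mode: str = "exact"  # consistency-check matching mode
    normalize: bool = True
    propagate: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def validate(self) -> None:
        required = {
            "go_obo": self.go_obo,
            "pheno_obo": self.pheno_obo,
            "gaf": self.gaf,
            "phenotype_tsv": self.phenotype_tsv,
        }
        optional = {
            "quality_config": self.quality_config,
            "predicted_functions": self.predicted_functions,
            "string_links": self.string_links,
        }
        for name, path in {**required, **{k: v for k, v in optional.items() if v}}.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"config path {name} does not exist: {path}")
        if self.mode not in ("exact", "inferred"):
            raise ValueError(f"mode must be exact|inferred, got {self.mode!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns (and writes) the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    for sub in ("rules", "findings", "predictions", "sim", "eval"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "tool": "phenorules",
        "version": __version__,
        "config": asdict(config),
        "inputs": {},
        "stages": {},
        "outputs": {},
        "complete": False,
    }
    for name in ("go_obo", "pheno_obo", "gaf", "phenotype_tsv",
                 "predicted_functions", "string_links", "quality_config"):
        path = getattr(config, name)
        if path:
            manifest["inputs"][name] = _sha256(Path(path))

    def stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - rethrown with stage context
            manifest["complete"] = False
            manifest["failed_stage"] = name
            _write_manifest(outdir, manifest)
            raise PipelineError(name, exc) from exc

    go = stage("load_go", lambda: load_obo(config.go_obo))
    pheno = stage("load_pheno", lambda: load_obo(config.pheno_obo))
    qc = (
        QualityConfig.from_yaml(config.quality_config)
        if config.quality_config
        else QualityConfig()
    )

    def _rules():
        regs = index_regulations(go)
        decs = decompose_all(pheno, qc)
        rules = build_correspondence_rules(regs, decs)
        patterns = build_inconsistency_patterns(regs, decs)
        with open(outdir / "rules" / "rules.tsv", "w") as fh:
            write_rules_tsv(rules, fh)
        with open(outdir / "rules" / "patterns.tsv", "w") as fh:
            write_rules_tsv(patterns, fh)
        return regs, decs, rules, patterns

    regs, decs, rules, patterns = stage("rules", _rules)
    manifest["stages"]["rules"] = {
        "regulations": len(regs), "eq_decompositions": len(decs),
        "rules": len(rules), "patterns": len(patterns),
    }

    functions = stage("load_functions", lambda: parse_gaf(config.gaf))
    phenotypes = stage(
        "load_phenotypes",
        lambda: parse_phenotype_tsv(
            config.phenotype_tsv, dialect=config.phenotype_dialect),
    )
    manifest["stages"]["load"] = {
        "function_genes": len(functions.genes),
        "function_annotations": functions.n_annotations(),
        "phenotype_genes": len(phenotypes.genes),
        "phenotype_annotations": phenotypes.n_annotations(),
    }

    def _check():
        findings = check_corpus(
            functions, phenotypes, patterns, mode=config.mode,
            graph=go.merged_with(pheno))
        with open(outdir / "findings" / "findings.tsv", "w") as fh:
            write_findings_tsv(findings, fh)
        return findings

    findings = stage("check", _check)
    manifest["stages"]["check"] = {
        "findings": len(findings), "mode": config.mode}

    def _predict():
        preds = predict(functions, rules)
        found, novel = split_novel(preds, phenotypes, pheno, match="inferred")
        with open(outdir / "predictions" / "predictions.tsv", "w") as fh:
            write_predictions_tsv(preds, fh)
        with open(outdir / "predictions" / "found.tsv", "w") as fh:
            write_predictions_tsv(found, fh)
        with open(outdir / "predictions" / "novel.tsv", "w") as fh:
            write_predictions_tsv(novel, fh)
        return preds, found, novel

    preds, found, novel = stage("predict", _predict)
    manifest["stages"]["predict"] = {
        "predictions": len(preds), "found": len(found), "novel": len(novel)}

    def _sim():
        merged = phenotypes.merged_with(predictions_as_corpus(preds))
        ic = information_content(merged, pheno)
        matrix = gene_similarity_matrix(merged, ic, pheno,
                                        normalize=config.normalize)
        with open(outdir / "sim" / "ic.tsv", "w") as fh:
            write_ic_tsv(ic, fh)
        with open(outdir / "sim" / "similarity.tsv", "w") as fh:
            matrix.write_tsv(fh)
        return ic, matrix

    ic, matrix = stage("sim", _sim)
    manifest["stages"]["sim"] = {
        "genes": len(matrix.genes), "ic_classes": len(ic.ic)}

    def _eval():
        results: dict = {}
        if preds and phenotypes.genes:
            fr = fmax(preds, phenotypes, pheno)
            results["fmax"] = {
                "fmax": fr.fmax, "best_threshold": fr.best_threshold, "n": fr.n}
            with open(outdir / "eval" / "fmax.json", "w") as fh:
                json.dump({**results["fmax"],
                           "curve": fr.curve}, fh, indent=1)
        if config.string_links:
            positives = parse_string_links(
                config.string_links, min_score=config.min_string_score)
            scores = matrix.pair_scores()
            positives &= set(scores)
            rr = roc_auc(scores, positives)
            results["roc"] = {
                "auc": rr.auc, "positives": rr.positives,
                "negatives": rr.negatives}
            with open(outdir / "eval" / "roc.json", "w") as fh:
                json.dump(results["roc"], fh, indent=1)
        return results

    manifest["stages"]["eval"] = stage("eval", _eval)

    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(outdir))] = _sha256(path)
    manifest["complete"] = True
    _write_manifest(outdir, manifest)
    return manifest


def _write_manifest(outdir: Path, manifest: dict) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
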