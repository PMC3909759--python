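"""End-to-end workflows: the six-step training wizard and diagnostic mode.

``run_training_workflow`` executes dataset loading, gene ranking,
enrichment with filtering, grid evaluation, expert selection, final
committee training and persistence from a single flat configuration
mapping; ``run_diagnostic_workflow`` applies a saved committee to new
samples. Both write a JSON run manifest (tool version, full parameter
record, input digests, timestamps) sufficient to re-execute the run
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

from . import __version__
from . import committee as committee_mod
from . import data_io, diagnostic, enrichment, evaluation, feature_ranking

log = logging.getLogger("genesetcommittee")


class WorkflowError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path: str | Path, subcommand: str, params: Mapping[str, Any],
                   inputs: Mapping[str, str | Path]) -> dict[str, Any]:
    manifest = {
        "tool": "genesetcommittee",
        "version": __version__,
        "subcommand": subcommand,
        "parameters": dict(params),
        "input_digests": {name: _digest(p) for name, p in inputs.items()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    Path(path).write_text(json.dumps(manifest, indent=1, default=str) + "\n",
                          encoding="utf-8")
    return manifest


@dataclass
class TrainingResult:
    committee: committee_mod.Committee
    grid: evaluation.EvaluationGrid
    ranked: feature_ranking.RankedGeneList
    enriched: list[enrichment.EnrichedGeneSet]


TRAINING_DEFAULTS: dict[str, Any] = {
    "method": "chi_squared",
    "n_top": 50,
    "binarize": False,
    "merge_missing": False,
    "relief_neighbors": 1,
    "relief_iterations": "all",
    "max_p": None,
    "min_coverage": 0,
    "name_pattern": None,
    "sources": None,
    "classifiers": None,          # None -> one default config per family
    "scheme": "stratified_kfold",
    "folds": 5,
    "seed": 17,
    "select": "top:10",           # "top:K" or "kappa>=X"
    "n_workers": 1,
}


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        start = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise WorkflowError(f"stage {name!r} failed: {exc}") from exc
        log.info("stage %s finished in %.2fs", name, time.perf_counter() - start)
        return result

    return wrap


def parse_selection_rule(text: str) -> committee_mod.SelectionRule:
    """Parse ``top:K`` or ``<metric>>=X`` selection syntax (e.g. ``kappa>=0.95``)."""
    text = text.strip()
    if text.startswith("top:"):
        return committee_mod.top_k(int(text[4:]))
    if ">=" in text:
        metric, value = text.split(">=", 1)
        return committee_mod.threshold(metric.strip(), float(value))
    raise ValueError(f"unparseable selection rule {text!r}")


def build_configs(spec: Any, seed: int) -> list[evaluation.ClassifierConfig]:
    """Classifier configs from None (defaults), a JSON file path, or a list of dicts."""
    if spec is None:
        return evaluation.default_classifier_configs()
    if isinstance(spec, (str, Path)):
        spec = json.loads(Path(spec).read_text(encoding="utf-8"))
    configs = []
    for entry in spec:
        configs.append(
            evaluation.ClassifierConfig(
                family=entry["family"],
                hyperparameters=entry.get("hyperparameters", {}),
                config_id=entry.get("config_id", ""),
            )
        )
    return configs


def run_training_workflow(config: Mapping[str, Any],
                          committee_path: str | Path,
                          manifest_path: str | Path | None = None) -> TrainingResult:
    """Execute the full training pipeline from a flat configuration mapping.

    ``config`` must name ``input`` (expression CSV) and ``gmt`` (gene-set
    collection); all other keys default to :data:`TRAINING_DEFAULTS`.
    """
    params = dict(TRAINING_DEFAULTS)
    unknown = set(config) - set(params) - {"input", "gmt"}
    if unknown:
        raise WorkflowError(f"unknown configuration keys: {sorted(unknown)}")
    params.update(config)
    for key in ("input", "gmt"):
        if key not in params:
            raise WorkflowError(f"configuration misses required key {key!r}")

    dataset = _stage("load-dataset")(data_io.read_expression_matrix, params["input"])
    collection = _stage("load-gene-sets")(data_io.read_gene_set_collection, params["gmt"])

    ranking_config = feature_ranking.RankingConfig(
        method=feature_ranking.METHOD_ALIASES.get(params["method"], params["method"]),
        n_top=int(params["n_top"]),
        binarize=bool(params["binarize"]),
        merge_missing=bool(params["merge_missing"]),
        relief_neighbors=int(params["relief_neighbors"]),
        relief_iterations=params["relief_iterations"],
        seed=int(params["seed"]),
    )
    ranked = _stage("rank")(feature_ranking.rank_genes, dataset, ranking_config)

    enriched = _stage("enrich")(enrichment.enrich, ranked, collection, dataset)
    filtered = _stage("filter")(
        enrichment.filter_enriched,
        enriched,
        max_p=params["max_p"],
        min_coverage=int(params["min_coverage"]),
        name_pattern=params["name_pattern"],
        sources=params["sources"],
    )
    if not filtered:
        raise WorkflowError(
            "stage 'filter' failed: no candidate gene sets survive the filters"
        )

    configs = build_configs(params["classifiers"], int(params["seed"]))
    scheme = evaluation.ValidationScheme(
        kind=params["scheme"], folds=int(params["folds"]), seed=int(params["seed"])
    )
    grid = _stage("evaluate")(
        evaluation.evaluate_grid, dataset, filtered, configs, scheme,
        n_workers=int(params["n_workers"]),
    )
    log.info("grid: %d cells, %d ERROR", grid.n_cells, grid.error_count())

    rule = parse_selection_rule(params["select"])
    specs = _stage("select")(committee_mod.select_experts, grid, rule)
    built = _stage("train")(
        committee_mod.train_committee, dataset, specs, grid,
        metadata={
            "n_training_samples": dataset.n_samples,
            "n_genes": dataset.n_genes,
            "class_counts": dataset.class_counts(),
            "ranking": {"method": ranking_config.method, "n_top": ranking_config.n_top,
                        "binarize": ranking_config.binarize,
                        "merge_missing": ranking_config.merge_missing},
            "filters": {"max_p": params["max_p"], "min_coverage": params["min_coverage"],
                        "name_pattern": params["name_pattern"],
                        "sources": params["sources"]},
            "scheme": {"kind": scheme.kind, "folds": scheme.folds, "seed": scheme.seed},
            "selection": params["select"],
        },
    )
    _stage("persist")(data_io.persist_committee, built, committee_path)

    if manifest_path is not None:
        write_manifest(
            manifest_path, "train", params,
            {"input": params["input"], "gmt": params["gmt"]},
        )
    return TrainingResult(committee=built, grid=grid, ranked=ranked, enriched=filtered)


def run_diagnostic_workflow(committee_path: str | Path, patients_path: str | Path,
                            report_path: str | Path,
                            manifest_path: str | Path | None = None,
                            impute_missing: str | None = None) -> diagnostic.DiagnosticReport:
    """Apply a saved committee to new samples and write the diagnostic report CSV."""
    loaded = _stage("load-committee")(data_io.load_committee, committee_path)
    patients = _stage("load-patients")(data_io.read_expression_matrix, patients_path)
    report = _stage("diagnose")(
        diagnostic.build_report, loaded, patients, impute_missing=impute_missing
    )
    report.to_csv(report_path)
    if manifest_path is not None:
        write_manifest(
            manifest_path, "diagnose",
            {"committee": str(committee_path), "input": str(patients_path),
             "impute_missing": impute_missing},
            {"committee": committee_path, "input": patients_path},
        )
    return report
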