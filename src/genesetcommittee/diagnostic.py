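"""Committee diagnosis of new samples: per-expert predictions, grouped
summaries and unweighted majority voting with tie reporting.

The report mirrors the four-section diagnostic table: *Committee* (one row
per expert), *By Gene Set* and *By Classifier* (modal conditions within each
group), and *Voting* (vote counts per condition plus the final condition or
conditions with the most votes). Ties are always reported, never broken.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

from .committee import Committee
from .data_io import ExpressionDataset, FormatError, _open_text


@dataclass
class PredictionMatrix:
    """Per-expert predicted condition for every sample.

    ``expert_meta`` maps expert id -> (gene set name, classifier display
    name) and powers the grouped report sections.
    """

    expert_ids: list[str]
    sample_ids: list[str]
    predictions: list[list[str]]  # experts x samples
    expert_meta: dict[str, tuple[str, str]] = field(default_factory=dict)
    classes: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.predictions) != len(self.expert_ids) or any(
            len(row) != len(self.sample_ids) for row in self.predictions
        ):
            raise ValueError("prediction matrix shape mismatch")
        if self.classes is None:
            seen: dict[str, None] = {}
            for row in self.predictions:
                for p in row:
                    seen.setdefault(p, None)
            self.classes = list(seen)

    def column(self, sample_id: str) -> list[str]:
        j = self.sample_ids.index(sample_id)
        return [row[j] for row in self.predictions]

    def row(self, expert_id: str) -> list[str]:
        return self.predictions[self.expert_ids.index(expert_id)]


@dataclass
class VoteTally:
    """Unweighted vote counts for one sample; all maximizers are reported."""

    sample_id: str
    counts: dict[str, int]
    final_conditions: tuple[str, ...]

    @property
    def is_tie(self) -> bool:
        return len(self.final_conditions) > 1


@dataclass
class DiagnosticReport:
    predictions: PredictionMatrix
    by_gene_set: dict[str, dict[str, tuple[str, ...]]]  # group -> sample -> modal set
    by_classifier: dict[str, dict[str, tuple[str, ...]]]
    voting: list[VoteTally]

    @property
    def has_ties(self) -> bool:
        return any(t.is_tie for t in self.voting)

    def final_conditions(self) -> dict[str, tuple[str, ...]]:
        return {t.sample_id: t.final_conditions for t in self.voting}

    def to_csv(self, sink) -> None:
        """Write the four-section table with one column per sample."""
        handle, close = _open_text(sink, "w")
        try:
            writer = csv.writer(handle, lineterminator="\n")
            samples = self.predictions.sample_ids
            writer.writerow(["Section", "Row", *samples])
            for expert_id in self.predictions.expert_ids:
                writer.writerow(["Committee", expert_id, *self.predictions.row(expert_id)])
            for group, per_sample in self.by_gene_set.items():
                writer.writerow(
                    ["By Gene Set", group, *("/".join(per_sample[s]) for s in samples)]
                )
            for group, per_sample in self.by_classifier.items():
                writer.writerow(
                    ["By Classifier", group, *("/".join(per_sample[s]) for s in samples)]
                )
            tallies = {t.sample_id: t for t in self.voting}
            for condition in self.predictions.classes or []:
                writer.writerow(
                    ["Voting", condition,
                     *(tallies[s].counts.get(condition, 0) for s in samples)]
                )
            writer.writerow(
                ["Voting", "Condition",
                 *("/".join(tallies[s].final_conditions) for s in samples)]
            )
        finally:
            if close:
                handle.close()


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def predict_experts(committee: Committee, dataset: ExpressionDataset,
                    impute_missing: str | None = None) -> PredictionMatrix:
    """Run every committee expert on every sample of ``dataset``.

    Genes an expert needs but the dataset lacks are a hard error listing
    both the gene ids and the affected experts, unless
    ``impute_missing="training-mean"`` fills them with the stored training
    means.
    """
    if dataset.n_samples == 0:
        raise ValueError("diagnostic dataset has no samples")
    present = set(dataset.gene_ids)
    missing: dict[str, list[str]] = {}
    for gene, expert_ids in committee.required_genes().items():
        if gene not in present:
            missing[gene] = expert_ids
    if missing and impute_missing != "training-mean":
        detail = "; ".join(
            f"{g} (needed by {', '.join(ids)})" for g, ids in sorted(missing.items())
        )
        raise KeyError(f"diagnostic dataset is missing required genes: {detail}")

    work = dataset
    if missing:
        work = _augment_with_means(dataset, sorted(missing), committee.training_means)

    rows = [
        expert.predict(work, impute_means=committee.training_means)
        for expert in committee.experts
    ]
    meta = {
        e.expert_id: (e.gene_set.name, e.family_display) for e in committee.experts
    }
    return PredictionMatrix(
        expert_ids=[e.expert_id for e in committee.experts],
        sample_ids=list(dataset.sample_ids),
        predictions=rows,
        expert_meta=meta,
        classes=list(committee.classes),
    )


def _augment_with_means(dataset: ExpressionDataset, genes: Sequence[str],
                        means: Mapping[str, float]) -> ExpressionDataset:
    import numpy as np

    unknown = [g for g in genes if g not in means]
    if unknown:
        raise KeyError(f"no training mean recorded for genes: {', '.join(unknown)}")
    extra = np.tile(
        np.array([[means[g]] for g in genes]), (1, dataset.n_samples)
    )
    return ExpressionDataset(
        sample_ids=list(dataset.sample_ids),
        gene_ids=list(dataset.gene_ids) + list(genes),
        gene_names=list(dataset.gene_names) + list(genes),
        values=np.vstack([dataset.values, extra]),
        class_labels=list(dataset.class_labels) if dataset.class_labels else None,
    )


def _modal(votes: Sequence[str]) -> tuple[str, ...]:
    counts: dict[str, int] = {}
    for v in votes:
        counts[v] = counts.get(v, 0) + 1
    best = max(counts.values())
    return tuple(c for c in counts if counts[c] == best)


def tally_votes(pm: PredictionMatrix) -> list[VoteTally]:
    """Unweighted vote count per sample; final_conditions holds every maximizer."""
    tallies = []
    for sample_id in pm.sample_ids:
        column = pm.column(sample_id)
        counts: dict[str, int] = {c: 0 for c in (pm.classes or [])}
        for vote in column:
            counts[vote] = counts.get(vote, 0) + 1
        best = max(counts.values())
        final = tuple(c for c in counts if counts[c] == best)
        tallies.append(VoteTally(sample_id=sample_id, counts=counts, final_conditions=final))
    return tallies


def group_summary(pm: PredictionMatrix,
                  key: Literal["gene_set", "classifier_family"]
                  ) -> dict[str, dict[str, tuple[str, ...]]]:
    """Modal condition(s) per (group, sample), grouping experts by gene set
    or classifier family; ties are all reported."""
    if key not in ("gene_set", "classifier_family"):
        raise ValueError(f"unknown grouping key {key!r}")
    pos = 0 if key == "gene_set" else 1
    groups: dict[str, list[str]] = {}
    for expert_id in pm.expert_ids:
        if expert_id not in pm.expert_meta:
            raise ValueError(f"expert {expert_id!r} has no group metadata")
        groups.setdefault(pm.expert_meta[expert_id][pos], []).append(expert_id)
    summary: dict[str, dict[str, tuple[str, ...]]] = {}
    for group, members in groups.items():
        per_sample: dict[str, tuple[str, ...]] = {}
        for j, sample_id in enumerate(pm.sample_ids):
            per_sample[sample_id] = _modal([pm.row(e)[j] for e in members])
        summary[group] = per_sample
    return summary


def build_report(committee: Committee, dataset: ExpressionDataset,
                 impute_missing: str | None = None) -> DiagnosticReport:
    """Classify ``dataset`` and assemble the four-section diagnostic report."""
    pm = predict_experts(committee, dataset, impute_missing=impute_missing)
    return report_from_predictions(pm)


def report_from_predictions(pm: PredictionMatrix) -> DiagnosticReport:
    """Assemble a report from an existing expert-prediction matrix."""
    return DiagnosticReport(
        predictions=pm,
        by_gene_set=group_summary(pm, "gene_set"),
        by_classifier=group_summary(pm, "classifier_family"),
        voting=tally_votes(pm),
    )


# ---------------------------------------------------------------------------
# Prediction-matrix CSV import and the packaged demo fixture
# ---------------------------------------------------------------------------

def read_prediction_matrix(source) -> PredictionMatrix:
    """Read an expert-prediction matrix CSV.

    Layout: header ``expert_id,classifier,gene_set,<sample id>,...`` then one
    row per expert with its predictions.
    """
    handle, close = _open_text(source)
    try:
        rows = [r for r in csv.reader(handle) if r]
    finally:
        if close:
            handle.close()
    if not rows or len(rows[0]) < 4:
        raise FormatError(
            "prediction matrix needs header expert_id,classifier,gene_set,<samples...>"
        )
    sample_ids = [c.strip() for c in rows[0][3:]]
    expert_ids: list[str] = []
    predictions: list[list[str]] = []
    meta: dict[str, tuple[str, str]] = {}
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(rows[0]):
            raise FormatError(f"prediction matrix row {i} is ragged")
        expert_id, classifier, gene_set = (c.strip() for c in row[:3])
        if expert_id in meta:
            raise FormatError(f"duplicate expert ID: {expert_id!r}")
        expert_ids.append(expert_id)
        meta[expert_id] = (gene_set, classifier)
        predictions.append([c.strip() for c in row[3:]])
    return PredictionMatrix(
        expert_ids=expert_ids,
        sample_ids=sample_ids,
        predictions=predictions,
        expert_meta=meta,
    )


def load_demo_prediction_matrix() -> PredictionMatrix:
    """The packaged 10-expert x 12-sample AML demo prediction matrix.

    A committee of ten gene-set experts (decision trees, naive Bayes, random
    forest and nearest-neighbour classifiers over five biological concepts)
    applied to twelve held-out acute myeloid leukemia samples spanning the
    conditions LAP, INV, M5 and OTH.
    """
    path = resources.files("genesetcommittee").joinpath("data/aml_demo_predictions.csv")
    with path.open("r", encoding="utf-8") as handle:
        return read_prediction_matrix(handle)
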