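"""Expert selection from an evaluation grid and final committee training.

Selected experts are refit on the full training dataset (not the CV fold
models) using only their gene set's covered features; the CV metrics are
carried over as the expert's recorded performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

from .data_io import ExpressionDataset, GeneSet
from .evaluation import (
    ClassifierConfig,
    ErrorCell,
    EvaluationGrid,
    ExpertTrainingError,
    _impute_train_means,
)


@dataclass(frozen=True)
class ExpertSpec:
    """A selected grid cell: one gene set paired with one classifier config."""

    set_id: str
    config_id: str
    selection_metric_value: float


@dataclass(frozen=True)
class SelectionRule:
    """Either the k best cells by a metric or all cells at or above a threshold."""

    kind: str  # "top_k" | "threshold"
    metric: str = "kappa"
    k: int = 0
    min_value: float = 0.0


def top_k(k: int, metric: str = "kappa") -> SelectionRule:
    if k < 1:
        raise ValueError("top_k needs k >= 1")
    return SelectionRule(kind="top_k", metric=metric, k=k)


def threshold(metric: str, min_value: float) -> SelectionRule:
    return SelectionRule(kind="threshold", metric=metric, min_value=min_value)


def select_experts(grid: EvaluationGrid, rule: SelectionRule) -> list[ExpertSpec]:
    """Pick experts from non-ERROR grid cells.

    ``top_k`` orders by metric descending with ties resolved by row order
    then column order; ``threshold`` keeps every cell with metric >=
    min_value (inclusive, so a 0.95 cutoff keeps kappa = 0.95).
    """
    candidates: list[tuple[float, int, int]] = []
    for i, row in enumerate(grid.rows):
        for j, config in enumerate(grid.columns):
            value = grid.metric_value(i, j, rule.metric)
            if value is None:
                continue  # ERROR cells are never selectable
            candidates.append((value, i, j))

    if rule.kind == "top_k":
        candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
        chosen = candidates[: rule.k]
    elif rule.kind == "threshold":
        chosen = [c for c in candidates if c[0] >= rule.min_value]
    else:
        raise ValueError(f"unknown selection rule {rule.kind!r}")

    if not chosen:
        raise ValueError("committee would be empty: no cell satisfies the rule")
    return [
        ExpertSpec(
            set_id=grid.rows[i].set_id,
            config_id=grid.columns[j].config_id,
            selection_metric_value=float(v),
        )
        for v, i, j in chosen
    ]


@dataclass
class TrainedExpert:
    """A fitted classifier bound to one gene set, with its recorded CV metrics."""

    expert_id: str
    gene_set: GeneSet
    usable_features: tuple[str, ...]
    config: ClassifierConfig
    metrics: dict[str, float]
    model: Any
    feature_means: np.ndarray | None = None

    @property
    def family_display(self) -> str:
        from .evaluation import FAMILY_DISPLAY

        return FAMILY_DISPLAY[self.config.family]

    def predict(self, dataset: ExpressionDataset,
                impute_means: Mapping[str, float] | None = None) -> list[str]:
        """Predict one condition per sample of ``dataset``."""
        index = dataset.gene_index()
        missing = [g for g in self.usable_features if g not in index]
        if missing:
            raise KeyError(missing)
        x = dataset.feature_matrix(self.usable_features)
        if np.isnan(x).any():
            fill = (
                np.array([impute_means.get(g, np.nan) for g in self.usable_features])
                if impute_means is not None
                else self.feature_means
            )
            if fill is None or np.isnan(fill).any():
                raise ValueError(
                    f"expert {self.expert_id}: missing expression values and no "
                    "training means available for imputation"
                )
            x = np.where(np.isnan(x), fill, x)
        return [str(p) for p in self.model.predict(x)]


@dataclass
class Committee:
    """An ordered ensemble of trained experts sharing one class-label set."""

    experts: list[TrainedExpert]
    classes: list[str]
    gene_universe: list[str]
    training_means: dict[str, float]
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.experts:
            raise ValueError("a committee needs at least one expert")
        ids = [e.expert_id for e in self.experts]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate expert identity in committee")

    def __len__(self) -> int:
        return len(self.experts)

    def required_genes(self) -> dict[str, list[str]]:
        """Gene id -> expert ids that need it."""
        needed: dict[str, list[str]] = {}
        for e in self.experts:
            for g in e.usable_features:
                needed.setdefault(g, []).append(e.expert_id)
        return needed


def train_committee(dataset: ExpressionDataset, specs: Sequence[ExpertSpec],
                    grid: EvaluationGrid,
                    metadata: Mapping[str, Any] | None = None) -> Committee:
    """Refit each selected expert on the full training dataset.

    Expert identity is (set_id, config_id); duplicate specs are rejected.
    """
    dataset.require_training()
    if not specs:
        raise ValueError("no expert specs given")
    identities = [(s.set_id, s.config_id) for s in specs]
    if len(set(identities)) != len(identities):
        raise ValueError("duplicate expert identity in selection")

    rows = {r.set_id: r for r in grid.rows}
    cols = {c.config_id: c for c in grid.columns}
    experts: list[TrainedExpert] = []
    for spec in specs:
        enriched_set = rows[spec.set_id]
        config = cols[spec.config_id]
        cell = grid.cell(spec.set_id, spec.config_id)
        if isinstance(cell, ErrorCell):
            raise ValueError(
                f"expert ({spec.set_id}, {spec.config_id}) refers to an ERROR cell"
            )
        x = dataset.feature_matrix(enriched_set.usable_features)
        try:
            x_filled, means = _impute_train_means(x)
            model = config.build(random_state=grid.scheme.seed)
            model.fit(x_filled, np.asarray(dataset.class_labels))
        except Exception as exc:
            raise ExpertTrainingError(
                f"refit failed for expert ({spec.set_id}, {spec.config_id}): {exc}"
            ) from exc
        experts.append(
            TrainedExpert(
                expert_id=f"{spec.config_id}@{spec.set_id}",
                gene_set=enriched_set.gene_set,
                usable_features=enriched_set.usable_features,
                config=config,
                metrics=cell.as_flat_dict(),
                model=model,
                feature_means=means,
            )
        )

    training_means = {
        g: float(m)
        for e in experts
        for g, m in zip(e.usable_features, e.feature_means)
    }
    return Committee(
        experts=experts,
        classes=dataset.classes,
        gene_universe=list(dataset.gene_ids),
        training_means=training_means,
        metadata=dict(metadata or {}),
    )
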