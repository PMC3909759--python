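"""Discretization and gene ranking by class-discrimination.

Four filter methods are supported: the Pearson chi-square statistic of the
(bin x class) contingency table, information gain (bits), gain ratio, and
multiclass ReliefF. The first three operate on discretized expression
values — either a median split into two bins or equal-frequency terciles —
while ReliefF works on min-max-normalized continuous values with k nearest
hits/misses per class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .data_io import ExpressionDataset

RankingMethod = Literal["chi_squared", "info_gain", "gain_ratio", "relief_f"]

METHOD_ALIASES = {
    "chi2": "chi_squared",
    "chi_squared": "chi_squared",
    "infogain": "info_gain",
    "info_gain": "info_gain",
    "gainratio": "gain_ratio",
    "gain_ratio": "gain_ratio",
    "relieff": "relief_f",
    "relief_f": "relief_f",
}


@dataclass(frozen=True)
class RankingConfig:
    """Configuration of one ranking run.

    ``binarize`` switches discretization from equal-frequency terciles to a
    two-bin median split (ties fall in the lower bin). ``merge_missing``
    folds missing values into the populated bin whose mean is closest to the
    observed mean instead of giving them a bin of their own.
    ``relief_iterations`` may be ``"all"`` to visit every sample exactly once
    (seed-independent) or an integer m of seeded draws without replacement.
    """

    method: RankingMethod = "chi_squared"
    n_top: int = 50
    binarize: bool = False
    merge_missing: bool = False
    relief_neighbors: int = 1
    relief_iterations: int | str = "all"
    seed: int = 17

    def __post_init__(self) -> None:
        if self.method not in METHOD_ALIASES.values():
            raise ValueError(f"unknown ranking method {self.method!r}")
        if self.n_top < 1:
            raise ValueError("n_top must be >= 1")
        if self.relief_neighbors < 1:
            raise ValueError("relief_neighbors must be >= 1")
        if self.relief_iterations != "all" and (
            not isinstance(self.relief_iterations, int) or self.relief_iterations < 1
        ):
            raise ValueError("relief_iterations must be a positive integer or 'all'")


@dataclass
class RankedGeneList:
    """Top-N genes ordered by non-increasing score; ties keep input gene order."""

    entries: list[tuple[str, float]]
    config: RankingConfig
    gene_names: dict[str, str] = field(default_factory=dict)

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

def discretize(values: Sequence[float], class_labels: Sequence[str],
               config: RankingConfig) -> np.ndarray:
    """Map one gene's expression values to integer bins.

    Median split when ``binarize`` (values <= median go to bin 0), otherwise
    equal-frequency terciles. Constant genes collapse to a single bin.
    Missing values either join the populated bin whose mean is nearest the
    observed mean (``merge_missing``) or occupy a dedicated extra bin.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot discretize an empty vector")
    if len(class_labels) != x.size:
        raise ValueError("values and class labels differ in length")

    observed = x[~np.isnan(x)]
    bins = np.zeros(x.size, dtype=int)
    n_bins = 1
    if observed.size and np.nanmax(observed) > np.nanmin(observed):
        if config.binarize:
            median = float(np.median(observed))
            bins[~np.isnan(x)] = (x[~np.isnan(x)] > median).astype(int)
            n_bins = 2
        else:
            lo, hi = np.quantile(observed, [1 / 3, 2 / 3])
            obs_mask = ~np.isnan(x)
            b = np.zeros(obs_mask.sum(), dtype=int)
            v = x[obs_mask]
            b[v > lo] = 1
            b[v > hi] = 2
            bins[obs_mask] = b
            n_bins = 3
        # renumber so that only populated bins count, preserving order
        populated = np.unique(bins[~np.isnan(x)])
        remap = {old: new for new, old in enumerate(populated)}
        bins[~np.isnan(x)] = [remap[b] for b in bins[~np.isnan(x)]]
        n_bins = len(populated)

    missing = np.isnan(x)
    if missing.any():
        if config.merge_missing and observed.size:
            target = float(observed.mean())
            best = min(
                range(n_bins),
                key=lambda b: abs(float(observed[bins[~np.isnan(x)] == b].mean()) - target),
            )
            bins[missing] = best
        else:
            bins[missing] = n_bins  # dedicated missing bin
    return bins


# ---------------------------------------------------------------------------
# Contingency-table scores
# ---------------------------------------------------------------------------

def _contingency(bins: np.ndarray, labels: np.ndarray) -> np.ndarray:
    bin_values = np.unique(bins)
    classes = np.unique(labels)
    table = np.zeros((bin_values.size, classes.size), dtype=float)
    for i, b in enumerate(bin_values):
        for j, c in enumerate(classes):
            table[i, j] = np.sum((bins == b) & (labels == c))
    return table


def _chi_square_stat(table: np.ndarray) -> float:
    n = table.sum()
    if n == 0 or table.shape[0] < 2 or table.shape[1] < 2:
        return 0.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    mask = expected > 0
    return float(np.sum((table[mask] - expected[mask]) ** 2 / expected[mask]))


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _info_gain(table: np.ndarray) -> float:
    n = table.sum()
    if n == 0:
        return 0.0
    h_class = _entropy(table.sum(axis=0))
    h_cond = sum(
        (row.sum() / n) * _entropy(row) for row in table if row.sum() > 0
    )
    return max(0.0, h_class - h_cond)


def _gain_ratio(table: np.ndarray) -> float:
    h_bins = _entropy(table.sum(axis=1))
    if h_bins == 0.0:
        return 0.0
    return _info_gain(table) / h_bins


# ---------------------------------------------------------------------------
# ReliefF
# ---------------------------------------------------------------------------

def relief_f_weights(values: np.ndarray, labels: Sequence[str], *,
                     k: int = 1, m: int | str = "all", seed: int = 17) -> np.ndarray:
    """Multiclass ReliefF weights for a genes x samples matrix.

    Values are min-max normalized per gene; a comparison against a missing
    value contributes 0.5 to the per-gene difference. For each sampled
    instance the k nearest hits and, per other class, the k nearest misses
    (weighted by prior P(C)/(1 - P(class))) update the weights. ``m="all"``
    visits every sample once in order, making the result seed-independent.
    """
    x = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    n_genes, n_samples = x.shape
    if n_samples == 0:
        raise ValueError("empty dataset")

    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("ReliefF requires at least 2 classes")
    smallest = classes[np.argmin(counts)]
    if k >= counts.min():
        raise ValueError(
            f"relief_neighbors k={k} must be smaller than the smallest class "
            f"({smallest!r}, {counts.min()} samples)"
        )
    priors = {c: cnt / n_samples for c, cnt in zip(classes, counts)}

    # per-gene min-max normalization; constant genes get zero contribution
    all_missing = np.all(np.isnan(x), axis=1)
    with np.errstate(invalid="ignore"):
        lo = np.where(all_missing, 0.0, np.min(np.where(np.isnan(x), np.inf, x), axis=1))
        hi = np.where(all_missing, 0.0, np.max(np.where(np.isnan(x), -np.inf, x), axis=1))
    span = hi - lo
    safe_span = np.where(span > 0, span, 1.0)
    norm = (x - lo[:, None]) / safe_span[:, None]
    norm[span == 0, :] = 0.0  # constant genes never differ

    def gene_diff(i: int, j: int) -> np.ndarray:
        a, b = norm[:, i], norm[:, j]
        d = np.abs(a - b)
        miss = np.isnan(a) | np.isnan(b)
        d[miss] = 0.5
        d[span == 0] = 0.0
        return d

    distances = np.zeros((n_samples, n_samples))
    for i in range(n_samples):
        for j in range(i + 1, n_samples):
            d = gene_diff(i, j).sum()
            distances[i, j] = distances[j, i] = d

    if m == "all":
        picks = np.arange(n_samples)
    else:
        rng = np.random.default_rng(seed)
        picks = rng.choice(n_samples, size=min(int(m), n_samples), replace=False)
    m_eff = len(picks)

    weights = np.zeros(n_genes)
    for r in picks:
        cls = labels[r]
        order = np.argsort(distances[r], kind="stable")
        hits = [j for j in order if j != r and labels[j] == cls][:k]
        for h in hits:
            weights -= gene_diff(r, h) / (m_eff * k)
        for other in classes:
            if other == cls:
                continue
            misses = [j for j in order if labels[j] == other][:k]
            factor = priors[other] / (1.0 - priors[cls])
            for mi in misses:
                weights += factor * gene_diff(r, mi) / (m_eff * k)
    weights[span == 0] = 0.0
    return weights


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def score_genes(dataset: ExpressionDataset, config: RankingConfig) -> dict[str, float]:
    """Score every gene by the configured class-discrimination method."""
    dataset.require_training()
    labels = np.asarray(dataset.class_labels)

    if config.method == "relief_f":
        m = config.relief_iterations
        weights = relief_f_weights(
            dataset.values, labels, k=config.relief_neighbors, m=m, seed=config.seed
        )
        return dict(zip(dataset.gene_ids, (float(w) for w in weights)))

    scorer = {
        "chi_squared": _chi_square_stat,
        "info_gain": _info_gain,
        "gain_ratio": _gain_ratio,
    }[config.method]
    scores: dict[str, float] = {}
    for i, gene_id in enumerate(dataset.gene_ids):
        row = dataset.values[i]
        observed = row[~np.isnan(row)]
        if observed.size == 0 or np.all(observed == observed[0]):
            # constant (or fully missing) genes carry no class information
            scores[gene_id] = 0.0
            continue
        bins = discretize(row, labels, config)
        scores[gene_id] = scorer(_contingency(bins, labels))
    return scores


def rank_genes(dataset: ExpressionDataset, config: RankingConfig) -> RankedGeneList:
    """Return the top-N genes by score, ties broken by input gene order."""
    scores = score_genes(dataset, config)
    values = np.array([scores[g] for g in dataset.gene_ids])
    order = np.argsort(-values, kind="stable")[: min(config.n_top, len(values))]
    entries = [(dataset.gene_ids[i], float(values[i])) for i in order]
    names = dict(zip(dataset.gene_ids, dataset.gene_names))
    return RankedGeneList(entries=entries, config=config,
                          gene_names={g: names[g] for g, _ in entries})
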