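"""Over-representation scoring of top-ranked genes against a gene-set collection.

The p-value is the hypergeometric upper tail P(X >= overlap) where the
universe is restricted to dataset genes that appear anywhere in the
collection (the annotatable genes), the number of draws is the size of the
top-gene list intersected with that universe, and the successes in the
universe are the set's covered genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import hypergeom

from .data_io import ExpressionDataset, GeneSet, GeneSetCollection
from .feature_ranking import RankedGeneList


@dataclass
class EnrichedGeneSet:
    """A gene set scored against the ranked gene list.

    ``coverage`` counts set members present in the expression dataset;
    ``selected_overlap`` counts members that are also in the top-gene list;
    ``usable_features`` lists the covered members in dataset gene order, the
    exact features a downstream expert trains on.
    """

    gene_set: GeneSet
    p_value: float
    coverage: int
    selected_overlap: int
    usable_features: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (0 <= self.selected_overlap <= self.coverage <= len(self.gene_set.members)):
            raise ValueError(
                f"{self.gene_set.set_id}: overlap {self.selected_overlap} <= "
                f"coverage {self.coverage} <= {len(self.gene_set.members)} violated"
            )
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def set_id(self) -> str:
        return self.gene_set.set_id


def hypergeometric_upper_tail(overlap: int, universe: int, successes: int,
                              draws: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, successes, draws)."""
    if overlap <= 0:
        return 1.0
    return float(min(1.0, hypergeom.sf(overlap - 1, universe, successes, draws)))


def enrich(ranked: RankedGeneList, collection: GeneSetCollection,
           dataset: ExpressionDataset) -> list[EnrichedGeneSet]:
    """Score every collection set with coverage >= 1, sorted by ascending p-value.

    Ties in p-value are broken by set id so the output order is total and
    reproducible.
    """
    if len(ranked) == 0:
        raise ValueError("ranked gene list is empty")
    dataset_genes = list(dataset.gene_ids)
    annotated = collection.member_union()
    universe = [g for g in dataset_genes if g in annotated]
    if not universe:
        raise ValueError("no dataset gene appears in the collection")
    universe_set = set(universe)
    top = set(ranked.gene_ids)
    draws = len(top & universe_set)

    results: list[EnrichedGeneSet] = []
    for gene_set in collection:
        members = set(gene_set.members)
        usable = tuple(g for g in dataset_genes if g in members)
        coverage = len(usable)
        if coverage == 0:
            continue
        overlap = len(members & top & universe_set)
        p = hypergeometric_upper_tail(overlap, len(universe), coverage, draws)
        results.append(
            EnrichedGeneSet(
                gene_set=gene_set,
                p_value=p,
                coverage=coverage,
                selected_overlap=overlap,
                usable_features=usable,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.set_id))
    return results


def filter_enriched(results: Sequence[EnrichedGeneSet], *,
                    max_p: float | None = None,
                    min_coverage: int = 0,
                    name_pattern: str | None = None,
                    sources: Iterable[str] | None = None) -> list[EnrichedGeneSet]:
    """Keep sets with p_value < max_p (strict) and coverage >= min_coverage
    (inclusive), optionally restricted by case-insensitive name substring and
    source tag. Input order is preserved; filtering is idempotent."""
    allowed = set(sources) if sources is not None else None
    needle = name_pattern.lower() if name_pattern else None
    kept = []
    for r in results:
        if max_p is not None and not (r.p_value < max_p):
            continue
        if r.coverage < min_coverage:
            continue
        if needle is not None and needle not in r.gene_set.name.lower():
            continue
        if allowed is not None and r.gene_set.source not in allowed:
            continue
        kept.append(r)
    return kept
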