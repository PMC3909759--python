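import numpy as np
import pytest

import genesetcommittee as g


@pytest.fixture
def tiny_dataset() -> g.ExpressionDataset:
    """3 samples (classes A, A, B) x 2 genes, one missing value."""
    return g.ExpressionDataset(
        sample_ids=["S1", "S2", "S3"],
        gene_ids=["g1", "g2"],
        gene_names=["gene one", "gene two"],
        values=np.array([[1.0, 2.0, 3.0], [4.0, np.nan, 6.0]]),
        class_labels=["A", "A", "B"],
    )


@pytest.fixture
def aml_structured_dataset() -> g.ExpressionDataset:
    """Synthetic training dataset mirroring the four-condition AML structure:
    LAP 7, INV 3, M5 5, OTH 16 samples (31 total)."""
    spec = g.SyntheticSpec(
        classes={"LAP": 7, "INV": 3, "M5": 5, "OTH": 16},
        n_genes=60,
        signal_sets=[
            g.SignalSet("SET_LAP", tuple(f"G{i:04d}" for i in range(1, 11)),
                        {"LAP": 3.0}),
            g.SignalSet("SET_M5", tuple(f"G{i:04d}" for i in range(11, 21)),
                        {"M5": 3.0, "INV": -3.0}),
        ],
        seed=42,
    )
    return g.generate_dataset(spec)


@pytest.fixture
def separable_dataset() -> g.ExpressionDataset:
    """Two well-separated Gaussian classes; any reasonable learner separates them."""
    width = 4
    signal = g.SignalSet("SEP", tuple(f"G{i + 1:04d}" for i in range(10)), {"B": 6.0})
    spec = g.SyntheticSpec(classes={"A": 10, "B": 10}, n_genes=20,
                           signal_sets=[signal], sigma=0.5, seed=7)
    return g.generate_dataset(spec)


@pytest.fixture
def demo_predictions() -> g.PredictionMatrix:
    return g.load_demo_prediction_matrix()


@pytest.fixture
def trained_committee(separable_dataset) -> g.Committee:
    """A small committee of two experts trained on the separable dataset."""
    collection = g.GeneSetCollection([
        g.GeneSet("SEP", "Separating set", "signal",
                  tuple(f"G{i + 1:04d}" for i in range(10))),
        g.GeneSet("BG", "Background set", "null",
                  tuple(f"G{i + 11:04d}" for i in range(10))),
    ])
    ranked = g.rank_genes(separable_dataset,
                          g.RankingConfig(method="chi_squared", n_top=15))
    enriched = g.enrich(ranked, collection, separable_dataset)
    configs = [
        g.ClassifierConfig("knn", {"n_neighbors": 1}, "IBK#1"),
        g.ClassifierConfig("naive_bayes", {}, "NBS#1"),
    ]
    grid = g.evaluate_grid(separable_dataset, enriched, configs,
                           g.ValidationScheme(folds=5, seed=17))
    specs = g.select_experts(grid, g.top_k(2))
    return g.train_committee(separable_dataset, specs, grid)
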