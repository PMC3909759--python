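import numpy as np
import pytest

import genesetcommittee as g
from genesetcommittee.feature_ranking import (
    _chi_square_stat,
    _contingency,
    discretize,
    relief_f_weights,
)

from .oracles import relief_f_bruteforce


def make_dataset(values: np.ndarray, labels: list[str]) -> g.ExpressionDataset:
    n = values.shape[0]
    return g.ExpressionDataset(
        sample_ids=[f"S{j}" for j in range(values.shape[1])],
        gene_ids=[f"g{i}" for i in range(n)],
        gene_names=[f"g{i}" for i in range(n)],
        values=values,
        class_labels=labels,
    )


class TestDiscretize:
    def test_median_split(self):
        cfg = g.RankingConfig(binarize=True)
        bins = discretize([1, 2, 3, 4], ["A", "A", "B", "B"], cfg)
        assert bins.tolist() == [0, 0, 1, 1]

    def test_median_ties_go_low(self):
        cfg = g.RankingConfig(binarize=True)
        bins = discretize([1, 2, 2, 4], ["A", "A", "B", "B"], cfg)
        assert bins.tolist() == [0, 0, 0, 1]

    def test_constant_single_bin(self):
        cfg = g.RankingConfig(binarize=True)
        assert discretize([5, 5, 5], ["A", "A", "B"], cfg).tolist() == [0, 0, 0]

    def test_missing_gets_own_bin(self):
        cfg = g.RankingConfig(binarize=True, merge_missing=False)
        bins = discretize([1, np.nan, 4], ["A", "A", "B"], cfg)
        assert bins.tolist() == [0, 2, 1]

    def test_merge_missing_joins_populated_bin(self):
        cfg = g.RankingConfig(binarize=True, merge_missing=True)
        bins = discretize([1, np.nan, 4], ["A", "A", "B"], cfg)
        assert bins[1] in (0, 1)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            discretize([], [], g.RankingConfig())

    def test_terciles_by_default(self):
        cfg = g.RankingConfig(binarize=False)
        bins = discretize(list(range(9)), ["A"] * 9, cfg)
        assert sorted(set(bins.tolist())) == [0, 1, 2]


class TestContingencyScores:
    def test_perfect_two_class_gene(self):
        # binarized value equals the class in a balanced 20-sample dataset
        values = np.array([[0.0] * 10 + [1.0] * 10])
        labels = ["A"] * 10 + ["B"] * 10
        ds = make_dataset(values, labels)
        cfg = g.RankingConfig(method="chi_squared", binarize=True)
        assert g.score_genes(ds, cfg)["g0"] == pytest.approx(20.0)
        assert g.score_genes(ds, g.RankingConfig(method="info_gain", binarize=True))[
            "g0"
        ] == pytest.approx(1.0)
        assert g.score_genes(ds, g.RankingConfig(method="gain_ratio", binarize=True))[
            "g0"
        ] == pytest.approx(1.0)

    @pytest.mark.parametrize("method", ["chi_squared", "info_gain", "gain_ratio",
                                        "relief_f"])
    def test_constant_gene_scores_zero(self, method):
        values = np.vstack([np.full(8, 3.14), np.arange(8.0)])
        ds = make_dataset(values, ["A"] * 4 + ["B"] * 4)
        cfg = g.RankingConfig(method=method, binarize=True)
        assert g.score_genes(ds, cfg)["g0"] == 0.0

    def test_chi_square_matches_textbook_on_2x2(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            table = rng.integers(0, 30, size=(2, 2)).astype(float)
            if table.sum() == 0 or (table.sum(axis=0) == 0).any() \
               or (table.sum(axis=1) == 0).any():
                continue
            n = table.sum()
            a, b, c, d = table.ravel()
            textbook = n * (a * d - b * c) ** 2 / (
                (a + b) * (c + d) * (a + c) * (b + d)
            )
            assert _chi_square_stat(table) == pytest.approx(textbook, abs=1e-9)

    def test_score_invariants(self, aml_structured_dataset):
        for method, check in [
            ("chi_squared", lambda s: s >= 0),
            ("info_gain", lambda s: s >= 0),
            ("gain_ratio", lambda s: 0 <= s <= 1),
        ]:
            scores = g.score_genes(aml_structured_dataset,
                                   g.RankingConfig(method=method))
            assert all(np.isfinite(v) and check(v) for v in scores.values())

    def test_single_class_rejected(self):
        ds = make_dataset(np.arange(4.0).reshape(1, 4), ["A"] * 4)
        with pytest.raises(ValueError):
            g.score_genes(ds, g.RankingConfig())

    def test_permuted_labels_drive_scores_to_null(self):
        """Permuting class labels on a signal gene should, on average, give
        scores indistinguishable from a null gene (one-sample check over 100
        permutations)."""
        rng = np.random.default_rng(5)
        values = np.array([[0.0] * 10 + [3.0] * 10]) + rng.normal(0, 0.5, (1, 20))
        labels = ["A"] * 10 + ["B"] * 10
        ds = make_dataset(values, labels)
        cfg = g.RankingConfig(method="info_gain", binarize=True)
        signal_score = g.score_genes(ds, cfg)["g0"]
        perm_scores = []
        for _ in range(100):
            shuffled = list(labels)
            rng.shuffle(shuffled)
            perm_scores.append(
                g.score_genes(make_dataset(values, shuffled), cfg)["g0"]
            )
        # permuted scores collapse far below the planted-signal score
        assert np.mean(perm_scores) < 0.5 * signal_score
        # and a null gene's score distribution is centred near zero
        assert np.mean(perm_scores) < 0.25


class TestReliefF:
    def test_four_sample_worked_case(self):
        values = np.array([[0.0, 0.0, 1.0, 1.0]])
        weights = relief_f_weights(values, ["A", "A", "B", "B"], k=1, m="all")
        assert weights[0] == pytest.approx(1.0)

    def test_matches_bruteforce_on_small_datasets(self):
        rng = np.random.default_rng(11)
        for trial in range(20):
            n_samples = int(rng.integers(4, 13))
            n_genes = int(rng.integers(1, 6))
            labels = ["A", "A", "B", "B"] + [
                str(rng.choice(["A", "B", "C"])) for _ in range(n_samples - 4)
            ]
            values = rng.normal(0, 1, (n_genes, n_samples))
            if rng.random() < 0.3:
                values[rng.integers(n_genes), rng.integers(n_samples)] = np.nan
            counts = {c: labels.count(c) for c in set(labels)}
            if min(counts.values()) < 2:
                continue
            mine = relief_f_weights(values, labels, k=1, m="all")
            ref = relief_f_bruteforce(values, labels, k=1)
            np.testing.assert_allclose(mine, ref, atol=1e-12)

    def test_seeded_subsampling_reproducible(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0, 1, (5, 12))
        labels = ["A"] * 6 + ["B"] * 6
        w1 = relief_f_weights(values, labels, k=2, m=6, seed=99)
        w2 = relief_f_weights(values, labels, k=2, m=6, seed=99)
        np.testing.assert_array_equal(w1, w2)

    def test_k_too_large_names_class(self):
        values = np.zeros((1, 5))
        with pytest.raises(ValueError, match="B"):
            relief_f_weights(values, ["A", "A", "A", "B", "B"], k=2, m="all")


class TestRankGenes:
    def test_stable_tie_break(self):
        # g0 and g2 tie with a perfect association; g1 carries none
        values = np.array([[0, 0, 5, 5], [0, 5, 0, 5], [0, 0, 5, 5]], dtype=float)
        ds = make_dataset(values, ["A", "A", "B", "B"])
        ranked = g.rank_genes(ds, g.RankingConfig(method="chi_squared",
                                                  binarize=True, n_top=2))
        assert ranked.gene_ids == ["g0", "g2"]

    def test_n_larger_than_gene_count_returns_all(self, tiny_dataset):
        ranked = g.rank_genes(tiny_dataset, g.RankingConfig(n_top=50))
        assert len(ranked) == tiny_dataset.n_genes

    def test_scores_non_increasing(self, aml_structured_dataset):
        ranked = g.rank_genes(aml_structured_dataset, g.RankingConfig(n_top=30))
        scores = [s for _, s in ranked.entries]
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    @pytest.mark.parametrize("method", ["chi_squared", "info_gain", "gain_ratio",
                                        "relief_f"])
    def test_planted_genes_outrank_null_genes(self, method):
        ds, _, _ = g.make_recovery_scenario(seed=2, n_genes=60, n_null_sets=0,
                                            delta=4.0)
        signal = {f"G{i + 1:04d}" for i in range(10)}
        ranked = g.rank_genes(ds, g.RankingConfig(method=method, n_top=10))
        assert set(ranked.gene_ids) == signal
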