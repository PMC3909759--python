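import io
import itertools

import numpy as np
import pytest

import genesetcommittee as g

SAMPLES = ["AP13058", "AP14398", "AP5204", "BP7644", "CP13774", "CP9949",
           "XP12570", "XP15833", "XP170", "XP17273", "XP6209", "XP9875"]

EXPECTED_FINAL = ["LAP", "LAP", "LAP", "INV", "M5", "M5",
                  "OTH", "OTH", "OTH", "OTH", "OTH", "OTH"]


class TestVoting:
    def test_demo_tallies_match_printed_counts(self, demo_predictions):
        tallies = {t.sample_id: t for t in g.tally_votes(demo_predictions)}
        assert tallies["AP13058"].counts == {"LAP": 9, "OTH": 1, "INV": 0, "M5": 0}
        assert tallies["AP13058"].final_conditions == ("LAP",)
        assert tallies["BP7644"].counts == {"INV": 7, "OTH": 3, "LAP": 0, "M5": 0}
        assert tallies["BP7644"].final_conditions == ("INV",)

    def test_demo_full_vote_rows(self, demo_predictions):
        tallies = {t.sample_id: t for t in g.tally_votes(demo_predictions)}
        expected_rows = {
            "INV": [0, 0, 1, 7, 1, 0, 1, 0, 1, 0, 2, 1],
            "M5": [0, 0, 0, 0, 7, 10, 3, 3, 0, 0, 0, 1],
            "LAP": [9, 9, 9, 0, 0, 0, 0, 2, 0, 3, 2, 0],
            "OTH": [1, 1, 0, 3, 2, 0, 6, 5, 9, 7, 6, 8],
        }
        for condition, row in expected_rows.items():
            assert [tallies[s].counts.get(condition, 0) for s in SAMPLES] == row

    def test_demo_final_condition_row(self, demo_predictions):
        finals = [t.final_conditions for t in g.tally_votes(demo_predictions)]
        assert [f[0] for f in finals] == EXPECTED_FINAL
        assert all(len(f) == 1 for f in finals)

    def test_ensemble_dominance(self, demo_predictions):
        """The majority vote is right for all 12 samples while no single
        expert row matches the final conditions everywhere."""
        finals = [t.final_conditions[0] for t in g.tally_votes(demo_predictions)]
        assert finals == EXPECTED_FINAL
        for expert_id in demo_predictions.expert_ids:
            assert demo_predictions.row(expert_id) != EXPECTED_FINAL

    def test_counts_sum_to_committee_size(self, demo_predictions):
        for tally in g.tally_votes(demo_predictions):
            assert sum(tally.counts.values()) == len(demo_predictions.expert_ids)
            assert tally.final_conditions

    def test_tie_reported_not_broken(self):
        pm = g.PredictionMatrix(
            expert_ids=["E1", "E2"], sample_ids=["S1"],
            predictions=[["A"], ["B"]],
            expert_meta={"E1": ("gs1", "knn"), "E2": ("gs2", "knn")},
        )
        tally = g.tally_votes(pm)[0]
        assert tally.counts == {"A": 1, "B": 1}
        assert set(tally.final_conditions) == {"A", "B"}
        assert tally.is_tie

    def test_vote_counts_invariant_to_expert_order(self, demo_predictions):
        pm = demo_predictions
        reorder = list(reversed(range(len(pm.expert_ids))))
        shuffled = g.PredictionMatrix(
            expert_ids=[pm.expert_ids[i] for i in reorder],
            sample_ids=pm.sample_ids,
            predictions=[pm.predictions[i] for i in reorder],
            expert_meta=pm.expert_meta,
            classes=pm.classes,
        )
        t1 = {t.sample_id: t.counts for t in g.tally_votes(pm)}
        t2 = {t.sample_id: t.counts for t in g.tally_votes(shuffled)}
        assert t1 == t2


class TestGroupSummary:
    def test_by_gene_set_modal(self, demo_predictions):
        summary = g.group_summary(demo_predictions, "gene_set")
        # DT#4, NBS#2, RF#1, IBK#3 share this concept and all vote M5 here
        assert summary["Regulation of cell shape"]["CP9949"] == ("M5",)

    def test_by_classifier_modal(self, demo_predictions):
        summary = g.group_summary(demo_predictions, "classifier_family")
        assert summary["Decision Tree"]["XP170"] == ("OTH",)

    def test_group_tie_shows_both(self):
        pm = g.PredictionMatrix(
            expert_ids=["E1", "E2"], sample_ids=["S1"],
            predictions=[["A"], ["B"]],
            expert_meta={"E1": ("gs", "knn"), "E2": ("gs", "svm")},
        )
        summary = g.group_summary(pm, "gene_set")
        assert set(summary["gs"]["S1"]) == {"A", "B"}

    def test_unknown_key_rejected(self, demo_predictions):
        with pytest.raises(ValueError):
            g.group_summary(demo_predictions, "zodiac_sign")


class TestPredictExperts:
    def test_shape_and_determinism(self, trained_committee, separable_dataset):
        pm1 = g.predict_experts(trained_committee, separable_dataset)
        pm2 = g.predict_experts(trained_committee, separable_dataset)
        assert len(pm1.expert_ids) == len(trained_committee)
        assert pm1.sample_ids == separable_dataset.sample_ids
        assert pm1.predictions == pm2.predictions
        for row in pm1.predictions:
            assert set(row) <= set(trained_committee.classes)

    def test_missing_gene_error_names_gene_and_expert(self, trained_committee,
                                                      separable_dataset):
        needed = trained_committee.experts[0].usable_features[0]
        keep = [i for i, gid in enumerate(separable_dataset.gene_ids)
                if gid != needed]
        reduced = g.ExpressionDataset(
            sample_ids=separable_dataset.sample_ids,
            gene_ids=[separable_dataset.gene_ids[i] for i in keep],
            gene_names=[separable_dataset.gene_names[i] for i in keep],
            values=separable_dataset.values[keep, :],
        )
        with pytest.raises(KeyError) as err:
            g.predict_experts(trained_committee, reduced)
        assert needed in str(err.value)
        assert trained_committee.experts[0].expert_id in str(err.value)

    def test_missing_gene_imputed_on_request(self, trained_committee,
                                             separable_dataset):
        needed = trained_committee.experts[0].usable_features[0]
        keep = [i for i, gid in enumerate(separable_dataset.gene_ids)
                if gid != needed]
        reduced = g.ExpressionDataset(
            sample_ids=separable_dataset.sample_ids,
            gene_ids=[separable_dataset.gene_ids[i] for i in keep],
            gene_names=[separable_dataset.gene_names[i] for i in keep],
            values=separable_dataset.values[keep, :],
        )
        pm = g.predict_experts(trained_committee, reduced,
                               impute_missing="training-mean")
        assert len(pm.sample_ids) == separable_dataset.n_samples


class TestReport:
    def test_report_sections_and_csv(self, demo_predictions, tmp_path):
        report = g.report_from_predictions(demo_predictions)
        assert not report.has_ties
        assert [report.final_conditions()[s][0] for s in SAMPLES] == EXPECTED_FINAL
        path = tmp_path / "report.csv"
        report.to_csv(path)
        text = path.read_text()
        lines = text.splitlines()
        assert lines[0].split(",")[2:] == SAMPLES
        sections = {line.split(",")[0] for line in lines[1:]}
        assert sections == {"Committee", "By Gene Set", "By Classifier", "Voting"}
        final_row = [l for l in lines if l.startswith("Voting,Condition")][0]
        assert final_row.split(",")[2:] == EXPECTED_FINAL

    def test_full_report_from_committee(self, trained_committee, separable_dataset):
        report = g.build_report(trained_committee, separable_dataset)
        assert len(report.voting) == separable_dataset.n_samples
        for tally in report.voting:
            assert sum(tally.counts.values()) == len(trained_committee)

    def test_empty_sample_set_rejected(self, trained_committee):
        empty = g.ExpressionDataset(
            sample_ids=[], gene_ids=["G0001"], gene_names=["G0001"],
            values=np.empty((1, 0)),
        )
        with pytest.raises(ValueError):
            g.build_report(trained_committee, empty)


class TestPredictionMatrixIO:
    def test_roundtrip_through_csv(self, demo_predictions, tmp_path):
        # write in the import format and read back
        path = tmp_path / "pm.csv"
        with open(path, "w") as fh:
            fh.write("expert_id,classifier,gene_set," + ",".join(SAMPLES) + "\n")
            for eid in demo_predictions.expert_ids:
                gs, fam = demo_predictions.expert_meta[eid]
                fh.write(",".join([eid, fam, gs] + demo_predictions.row(eid)) + "\n")
        back = g.read_prediction_matrix(path)
        assert back.predictions == demo_predictions.predictions
        assert back.expert_meta == demo_predictions.expert_meta

    def test_ragged_row_rejected(self):
        text = "expert_id,classifier,gene_set,S1,S2\nE1,knn,gs,A\n"
        with pytest.raises(g.FormatError, match="row 2"):
            g.read_prediction_matrix(io.StringIO(text))

    def test_duplicate_expert_rejected(self):
        text = ("expert_id,classifier,gene_set,S1\n"
                "E1,knn,gs,A\nE1,svm,gs,B\n")
        with pytest.raises(g.FormatError, match="E1"):
            g.read_prediction_matrix(io.StringIO(text))
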