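"""Interactor scoring: detection statistics, background subtraction and
the three-tier category assignment with cross-organ promotion."""

from math import comb

import pandas as pd
import pytest

from pulldown.config import ScoringThresholds
from pulldown.scoring import (
    assign_categories,
    combined_interactome,
    detection_pvalue,
    interactomes_by_tissue,
    rate_ratio,
    score_runs,
)

from conftest import make_runs

EDGELESS = pd.DataFrame(columns=["protein_a", "protein_b", "source"])


def edges_of(*pairs):
    return pd.DataFrame(
        [(a, b, "database") for a, b in pairs],
        columns=["protein_a", "protein_b", "source"],
    )


def row(ev, tissue, protein):
    sub = ev[(ev["tissue"] == tissue) & (ev["protein"] == protein)]
    assert len(sub) == 1
    return sub.iloc[0]


class TestStatistics:
    def test_all_or_nothing_detection(self):
        runs = make_runs({("spleen", "KI"): {"X": [5] * 8}, ("spleen", "WT"): {"X": [0] * 8}})
        ev = score_runs(runs)
        r = row(ev, "spleen", "X")
        assert r["p_tissue"] == pytest.approx(1 / comb(16, 8))
        assert r["runs_detected_ki"] == 8 and r["runs_detected_wt"] == 0

    def test_symmetric_evidence_is_null(self):
        runs = make_runs(
            {("spleen", "KI"): {"X": [2, 2, 2, 2, 0, 0, 0, 0]},
             ("spleen", "WT"): {"X": [2, 2, 2, 2, 0, 0, 0, 0]}}
        )
        r = row(score_runs(runs), "spleen", "X")
        assert r["p_tissue"] > 0.5
        assert r["ratio_tissue"] == pytest.approx(1.0)

    def test_pseudocounted_ratio(self):
        # 40 peptides over 8 KI runs vs none in 8 WT runs: (5+0.5)/(0+0.5)
        runs = make_runs({("spleen", "KI"): {"X": [5] * 8}, ("spleen", "WT"): {"X": [0] * 8}})
        r = row(score_runs(runs), "spleen", "X")
        assert r["ratio_tissue"] == pytest.approx(11.0)

    def test_detection_pvalue_requires_runs(self):
        with pytest.raises(ValueError):
            detection_pvalue(1, 0, 1, 5)
        with pytest.raises(ValueError):
            rate_ratio(1, 5, 1, 0)

    def test_pooled_statistics_span_tissues(self):
        runs = make_runs(
            {("spleen", "KI"): {"X": [3] * 4}, ("spleen", "WT"): {"X": [0] * 4},
             ("thymus", "KI"): {"X": [3] * 4}, ("thymus", "WT"): {"X": [0] * 4}}
        )
        ev = score_runs(runs)
        r = row(ev, "spleen", "X")
        assert r["p_all"] == pytest.approx(detection_pvalue(8, 8, 0, 8))
        assert r["p_all"] < r["p_tissue"]

    def test_zero_peptides_means_zero_detections(self, scored_evidence):
        ev = scored_evidence
        assert ((ev["peptides_ki"] == 0) == (ev["runs_detected_ki"] == 0)).all()
        assert ((ev["peptides_wt"] == 0) == (ev["runs_detected_wt"] == 0)).all()
        assert (ev["runs_detected_ki"] <= ev["n_runs_ki"]).all()
        assert (ev["runs_detected_wt"] <= ev["n_runs_wt"]).all()


class TestBackgroundSubtraction:
    def test_mock_biased_protein_rejected(self):
        runs = make_runs(
            {("spleen", "KI"): {"X": [1, 1, 0, 0, 0, 0, 0, 0]},
             ("spleen", "WT"): {"X": [3, 3, 3, 3, 3, 3, 3, 3]}}
        )
        ev = assign_categories(score_runs(runs), EDGELESS)
        assert row(ev, "spleen", "X")["category"] == "REJECTED"

    def test_bait_never_rejected(self):
        runs = make_runs(
            {("spleen", "KI"): {"BAIT": [9] * 8}, ("spleen", "WT"): {"Z": [1] * 8}}
        )
        ev = assign_categories(score_runs(runs), EDGELESS, bait_id="BAIT")
        assert row(ev, "spleen", "BAIT")["category"] == "BAIT"

    def test_absent_from_ki_rejected(self):
        runs = make_runs(
            {("spleen", "KI"): {"X": [0] * 6}, ("spleen", "WT"): {"X": [1, 0, 0, 0, 0, 0]}}
        )
        ev = assign_categories(score_runs(runs), EDGELESS)
        assert row(ev, "spleen", "X")["category"] == "REJECTED"


class TestCategories:
    def make_two_tissue_runs(self):
        # X: statistical CORE in spleen, weakly detected in thymus.
        # Y: borderline in spleen (pooled-significant via thymus), edge rescue.
        # C: clean CORE in both (anchor for rescue edges).
        return make_runs(
            {
                ("spleen", "KI"): {
                    "X": [5, 5, 5, 5, 5, 5, 5, 5],
                    "C": [8, 8, 8, 8, 8, 8, 8, 8],
                    "Y": [2, 2, 2, 0, 0, 0, 0, 0],
                    "N": [2, 2, 2, 0, 0, 0, 0, 0],
                },
                ("spleen", "WT"): {
                    "X": [0] * 8, "C": [0] * 8, "Y": [0] * 8, "N": [0] * 8,
                },
                ("thymus", "KI"): {
                    "X": [12, 0, 0, 0, 0, 0, 0, 0],
                    "C": [8, 8, 8, 8, 8, 8, 8, 8],
                    "Y": [2, 2, 2, 0, 0, 0, 0, 0],
                },
                ("thymus", "WT"): {"X": [0] * 8, "C": [0] * 8, "Y": [0] * 8},
            }
        )

    def test_statistical_core_call(self):
        ev = assign_categories(score_runs(self.make_two_tissue_runs()), None)
        r = row(ev, "spleen", "X")
        assert r["category"] == "CORE" and not r["promoted"]

    def test_cross_organ_promotion(self):
        ev = assign_categories(score_runs(self.make_two_tissue_runs()), EDGELESS)
        r = row(ev, "thymus", "X")
        assert r["category"] == "CORE" and r["promoted"]
        # promotion needs detection: C is CORE everywhere it appears instead
        assert row(ev, "thymus", "C")["category"] == "CORE"

    def test_rescue_requires_core_edge(self):
        runs = self.make_two_tissue_runs()
        with_edge = assign_categories(score_runs(runs), edges_of(("Y", "C")))
        r = row(with_edge, "spleen", "Y")
        assert r["category"] in ("CAT2", "CAT3")
        no_edge = assign_categories(score_runs(runs), EDGELESS)
        assert row(no_edge, "spleen", "N")["category"] == "REJECTED"
        edge_to_noncore = assign_categories(score_runs(runs), edges_of(("N", "Y")))
        assert row(edge_to_noncore, "spleen", "N")["category"] == "REJECTED"

    def test_pooled_vs_detection_rescue_tiers(self):
        runs = self.make_two_tissue_runs()
        ev = assign_categories(score_runs(runs), edges_of(("Y", "C"), ("N", "C")))
        # Y is detected in both tissues: pooled evidence 6/16 vs 0/16 is
        # significant -> Category 2
        assert row(ev, "spleen", "Y")["category"] == "CAT2"
        # N is spleen-only: pooled 3/16 vs 0/16 is not, but 3 KI detections
        # with a KI-biased ratio plus the edge rescue it -> Category 3
        assert row(ev, "spleen", "N")["category"] == "CAT3"

    def test_category_partition(self, scored_evidence):
        ev = scored_evidence
        assert set(ev["category"]) <= {"BAIT", "CORE", "CAT2", "CAT3", "REJECTED"}
        # one row per (tissue, protein) means the tiers partition by design;
        # check the frame keeps that key unique
        assert not ev.duplicated(["tissue", "protein"]).any()
        assert (ev.loc[ev["category"] == "BAIT", "protein"] == "BAIT").all()

    def test_removing_edges_only_downgrades_rescues(self, study, scored_evidence):
        universe, _, runs, _ = study
        without = assign_categories(score_runs(runs), None)
        merged = scored_evidence.merge(
            without, on=["tissue", "protein"], suffixes=("_with", "_wo")
        )
        changed = merged[merged["category_with"] != merged["category_wo"]]
        assert set(changed["category_with"]) <= {"CAT2", "CAT3"}
        assert (changed["category_wo"] == "REJECTED").all()
        core_with = merged["category_with"] == "CORE"
        assert (merged.loc[core_with, "category_wo"] == "CORE").all()

    def test_recovers_planted_truth(self, study, scored_evidence, default_config):
        _, truth, _, _ = study
        core = interactomes_by_tissue(scored_evidence, core_only=True)
        tp = fp = fn = 0
        for organ in default_config.organs:
            called, planted = core[organ], truth.planted[organ]
            tp += len(called & planted)
            fp += len(called - planted)
            fn += len(planted - called)
        assert tp / (tp + fp) >= 0.9
        assert tp / (tp + fn) >= 0.9

    def test_combined_interactome_lists_organs(self, scored_evidence):
        comb_df = combined_interactome(scored_evidence)
        multi = comb_df[comb_df["n_organs"] >= 2]
        assert len(multi) >= 1
        assert (comb_df["best_category"].isin(["CORE", "CAT2", "CAT3"])).all()
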