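"""Simulation benchmark: generation contract, truth labels, FDR/ROC evaluation."""

import numpy as np
import pandas as pd
import pytest

from meltforms import (
    SimConfig,
    SimTruth,
    calibrate_q_threshold,
    detect_proteoforms,
    evaluate_fdr,
    roc_from_scores,
    simulate_benchmark,
)
from meltforms.detect import ProteoformAssignment
from meltforms.simulate import _curve


class TestSimConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_positive": 7},  # not divisible over 4 delta levels
            {"sigma_fc": -0.1},
            {"temperatures": (41.0, 41.0, 47.0)},
            {"tm_range": (60.0, 50.0)},
            {"tm_noise_mode": "bogus"},
            {"positive_split": 0.0},
            {"floor_value": 0.0},
        ],
    )
    def test_invalid_configs_rejected_before_generation(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs).validate()


class TestGeneration:
    def test_default_composition(self):
        cfg = SimConfig()
        tensor, truth = simulate_benchmark(
            SimConfig(n_negative=20, n_positive=8, peptides_per_protein=15), seed=0
        )
        # full default composition checked on the truth table directly
        assert cfg.n_negative == 1000 and cfg.n_positive == 200
        assert truth.proteins["is_positive"].sum() == 8
        counts = truth.proteins[truth.proteins["is_positive"]]["delta_tm"].value_counts()
        assert set(counts.index) == {1.0, 2.0, 3.0, 4.0}
        assert (counts == 2).all()

    def test_tensor_dimensional_contract(self):
        cfg = SimConfig(n_negative=5, n_positive=4, peptides_per_protein=7)
        tensor, truth = simulate_benchmark(cfg, seed=1)
        assert tensor.shape == (9 * 7, 20, 8)
        assert len(truth.peptide_map) == 9 * 7
        assert set(truth.peptide_map["true_proteoform"]) == {0, 1}

    def test_reference_column_is_one_before_noise(self):
        tm = np.array([[50.0, 55.0], [58.0, 60.0]])
        curves = _curve(tm, np.array([41.0, 44.0, 63.0]), 50.0)
        assert np.allclose(curves[..., 0], 1.0)
        assert np.all(np.diff(curves, axis=-1) <= 0)

    def test_noise_floor_enforced(self):
        cfg = SimConfig(n_negative=4, n_positive=4, peptides_per_protein=5,
                        sigma_fc=0.5, floor_value=1e-3)
        tensor, _ = simulate_benchmark(cfg, seed=2)
        # non-positive draws are forced to the floor; small positives survive
        assert tensor.x.min() > 0.0
        assert (tensor.x == 1e-3).any()

    def test_deterministic_for_fixed_seed(self):
        cfg = SimConfig(n_negative=6, n_positive=4, peptides_per_protein=6)
        t1, truth1 = simulate_benchmark(cfg, seed=7)
        t2, truth2 = simulate_benchmark(cfg, seed=7)
        np.testing.assert_array_equal(t1.x, t2.x)
        pd.testing.assert_frame_equal(truth1.proteins, truth2.proteins)

    def test_noiseless_negatives_collapse_to_single_group(self):
        cfg = SimConfig(n_negative=3, n_positive=4, peptides_per_protein=12,
                        sigma_tm=0.0, sigma_fc=0.0)
        tensor, truth = simulate_benchmark(cfg, seed=3)
        assignments = detect_proteoforms(tensor, seed=0)
        for pid in truth.proteins.loc[~truth.proteins["is_positive"], "protein_id"]:
            a = assignments[pid]
            assert [g for g, _ in a.groups] == [f"{pid}_0"]


def fake_truth(n_pos, n_neg):
    rows = [(f"P{i}", True, 1.0, 50.0) for i in range(n_pos)]
    rows += [(f"N{i}", False, 0.0, 50.0) for i in range(n_neg)]
    return SimTruth(
        proteins=pd.DataFrame(rows, columns=["protein_id", "is_positive",
                                             "delta_tm", "base_tm"]),
        peptide_map=pd.DataFrame(columns=["peptide_id", "protein_id",
                                          "true_proteoform"]),
    )


def fake_assignment(gene, n_groups, q=0.5):
    groups = [(f"{gene}_{i}", frozenset({f"{gene}x{i}a", f"{gene}x{i}b",
                                         f"{gene}x{i}c"}))
              for i in range(1, n_groups + 1)]
    if n_groups == 0:
        groups = [(f"{gene}_0", frozenset({f"{gene}x"}))]
    return ProteoformAssignment(gene, groups, q, True)


class TestEvaluateFdr:
    def test_confusion_arithmetic(self):
        truth = fake_truth(20, 10)
        detections = {}
        for i in range(20):
            detections[f"P{i}"] = fake_assignment(f"P{i}", 2 if i < 18 else 0)
        for i in range(10):
            detections[f"N{i}"] = fake_assignment(f"N{i}", 2 if i < 2 else 0)
        ev = evaluate_fdr(detections, truth)
        assert (ev["tp"], ev["fp"], ev["fn"]) == (18, 2, 2)
        assert ev["fdr"] == pytest.approx(0.1)

    def test_no_detections_is_zero_fdr_and_sensitivity(self):
        truth = fake_truth(4, 4)
        detections = {p: fake_assignment(p, 0)
                      for p in truth.proteins["protein_id"]}
        ev = evaluate_fdr(detections, truth)
        assert ev["fdr"] == 0.0 and ev["sensitivity"] == 0.0

    def test_unknown_protein_rejected(self):
        truth = fake_truth(1, 1)
        with pytest.raises(ValueError):
            evaluate_fdr({"GHOST": fake_assignment("GHOST", 2)}, truth)

    def test_counting_matches_hand_tally_on_seeded_run(self):
        cfg = SimConfig(n_negative=10, n_positive=8, peptides_per_protein=15)
        tensor, truth = simulate_benchmark(cfg, seed=11)
        assignments = detect_proteoforms(tensor, seed=11)
        ev = evaluate_fdr(assignments, truth)
        hand_detected = {g for g, a in assignments.items() if len(a.groups) >= 2}
        positives = truth.positive_ids()
        assert ev["tp"] == len(hand_detected & positives)
        assert ev["fp"] == len(hand_detected - positives)
        assert ev["fn"] == len(positives - hand_detected)


class TestRocFromScores:
    def test_perfect_separation(self):
        truth = fake_truth(3, 3)
        scores = {f"P{i}": 1.0 + i for i in range(3)}
        scores |= {f"N{i}": 0.1 * i for i in range(3)}
        _, _, auc = roc_from_scores(scores, truth)
        assert auc == pytest.approx(1.0)

    def test_identical_scores_are_chance(self):
        truth = fake_truth(3, 3)
        _, _, auc = roc_from_scores({p: 0.5 for p in truth.proteins["protein_id"]},
                                    truth)
        assert auc == pytest.approx(0.5)

    def test_rank_sum_oracle(self):
        truth = fake_truth(2, 2)
        scores = {"P0": 4.0, "P1": 2.0, "N0": 3.0, "N1": 1.0}  # pos ranks 1, 3
        _, _, auc = roc_from_scores(scores, truth)
        assert auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        truth = fake_truth(2, 0)
        with pytest.raises(ValueError):
            roc_from_scores({"P0": 1.0, "P1": 0.5}, truth)


class TestCalibrateThreshold:
    def build_tiered(self):
        """Nested detection tiers giving FDR (0.25, 0.12, 0.09, 0.01) at
        thresholds (1, 2, 3, 4)."""
        detections = {}
        rows = []

        def add(prefix, n, positive, q):
            for i in range(n):
                pid = f"{prefix}{i}"
                rows.append((pid, positive, 1.0 if positive else 0.0, 50.0))
                detections[pid] = fake_assignment(pid, 2, q=q)

        add("tp_d4_", 99, True, 5.0)      # detected at every threshold
        add("fp_d4_", 1, False, 5.0)
        add("tp_d3_", 83, True, 3.5)      # drop out above threshold 3
        add("fp_d3_", 17, False, 3.5)
        add("tp_d2_", 38, True, 2.5)
        add("fp_d2_", 12, False, 2.5)
        add("tp_d1_", 80, True, 1.5)
        add("fp_d1_", 70, False, 1.5)
        truth = SimTruth(
            proteins=pd.DataFrame(rows, columns=["protein_id", "is_positive",
                                                 "delta_tm", "base_tm"]),
            peptide_map=pd.DataFrame(columns=["peptide_id", "protein_id",
                                              "true_proteoform"]),
        )
        return detections, truth

    def test_least_stringent_threshold_reaching_target(self):
        detections, truth = self.build_tiered()
        chosen, table = calibrate_q_threshold(detections, truth,
                                              thresholds=[1.0, 2.0, 3.0, 4.0],
                                              target_fdr=0.10)
        np.testing.assert_allclose(table["fdr"], [0.25, 0.12, 0.09, 0.01])
        assert chosen == 3.0

    def test_all_correct_returns_loosest_grid_point(self):
        truth = fake_truth(5, 5)
        detections = {f"P{i}": fake_assignment(f"P{i}", 2, q=0.5) for i in range(5)}
        detections |= {f"N{i}": fake_assignment(f"N{i}", 0, q=0.0) for i in range(5)}
        chosen, table = calibrate_q_threshold(detections, truth,
                                              thresholds=[0.1, 0.2, 0.3])
        assert chosen == 0.1
        assert (table["fdr"] == 0.0).all()

    def test_unattainable_target_warns_and_returns_most_stringent(self, caplog):
        truth = fake_truth(1, 9)
        detections = {p: fake_assignment(p, 2, q=1.0)
                      for p in truth.proteins["protein_id"]}
        with caplog.at_level("WARNING"):
            chosen, _ = calibrate_q_threshold(detections, truth,
                                              thresholds=[0.1, 0.5],
                                              target_fdr=0.10)
        assert chosen == 0.5
        assert any("most stringent" in r.message for r in caplog.records)
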