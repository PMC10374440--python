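"""Detector: curve distances, similarity graphs, communities, acceptance rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meltforms import (
    DetectionParams,
    assign_proteoform_groups,
    build_gene_graph,
    detect_communities,
    detect_proteoforms,
    partition_modularity,
    similarity,
    summarize_proteoform_profiles,
    weighted_distance,
)
from meltforms.data import PeptideQuantMatrix

from conftest import (
    best_partition_oracle,
    graph_from_weights,
    make_gene_tensor,
    modularity_oracle,
    two_block_weights,
)


class TestWeightedDistance:
    def test_identical_profiles(self):
        x = np.array([[1.0, 0.7, 0.3]])
        assert weighted_distance(x, x) == 0.0

    def test_hand_evaluated_complete_pair(self):
        # one cell line, two temperatures, no missing: v/(N*K) = 1
        d = weighted_distance(np.array([[1.0, 0.6]]), np.array([[1.0, 0.2]]))
        assert d == pytest.approx(0.4, abs=1e-12)

    def test_masked_value_drops_term_and_shrinks(self):
        xi = np.array([[1.0, 0.6]])
        xj = np.array([[1.0, np.nan]])
        # only the equal references compare; the sum over valid terms is 0
        assert weighted_distance(xi, xj) == pytest.approx(0.0, abs=1e-12)

    def test_no_shared_values_is_undefined(self):
        xi = np.array([[1.0, np.nan]])
        xj = np.array([[np.nan, 0.5]])
        assert np.isnan(weighted_distance(xi, xj))

    def test_unbiased_scaling_completes_partial_grid(self):
        xi = np.array([[1.0, 0.6, np.nan, np.nan]])
        xj = np.array([[1.0, 0.2, np.nan, np.nan]])
        # v=2 of NK=4: published scaling shrinks, unbiased scales up
        d_pub = weighted_distance(xi, xj, scaling="as_published")
        d_unb = weighted_distance(xi, xj, scaling="unbiased")
        assert d_pub == pytest.approx(0.4 * np.sqrt(0.5))
        assert d_unb == pytest.approx(0.4 * np.sqrt(2.0))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        xi = rng.uniform(0, 1.2, (3, 4))
        xj = rng.uniform(0, 1.2, (3, 4))
        xi[rng.uniform(size=xi.shape) < 0.2] = np.nan
        assert weighted_distance(xi, xj) == weighted_distance(xj, xi)


class TestSimilarity:
    @pytest.mark.parametrize("d,expected", [(0.0, 1.0), (0.4, 1 / 1.4), (1e9, 1e-9)])
    def test_values(self, d, expected):
        assert similarity(d) == pytest.approx(expected, rel=1e-6)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            similarity(-0.1)


class TestBuildGeneGraph:
    def test_complete_graph_edge_count(self):
        curves = {f"P{i:02d}": [[1.0, 0.5 + 0.01 * i, 0.2]] for i in range(10)}
        t = make_gene_tensor(curves, [41.0, 50.0, 59.0], cell_lines=["A"])
        g = build_gene_graph("G", t)
        assert g.n_vertices == 10
        assert len(g.to_igraph().es) == 45

    def test_two_identical_peptides_weight_one(self):
        t = make_gene_tensor({"P1": [[1.0, 0.5]], "P2": [[1.0, 0.5]]}, [41.0, 50.0],
                             cell_lines=["A"])
        g = build_gene_graph("G", t)
        assert g.similarity[0, 1] == pytest.approx(1.0)

    def test_three_peptides_weights_from_distances(self):
        t = make_gene_tensor(
            {"P1": [[1.0, 0.6]], "P2": [[1.0, 0.6]], "P3": [[1.0, 0.2]]},
            [41.0, 50.0], cell_lines=["A"],
        )
        g = build_gene_graph("G", t)
        w = {frozenset({a, b}): g.similarity[i, j]
             for i, a in enumerate(g.peptide_ids)
             for j, b in enumerate(g.peptide_ids) if i < j}
        assert w[frozenset({"P1", "P2"})] == pytest.approx(1.0)
        assert w[frozenset({"P1", "P3"})] == pytest.approx(1 / 1.4)
        assert w[frozenset({"P2", "P3"})] == pytest.approx(1 / 1.4)

    def test_single_peptide_gene_not_graphable(self):
        t = make_gene_tensor({"P1": [[1.0, 0.5]]}, [41.0, 50.0], cell_lines=["A"])
        with pytest.raises(ValueError, match="not graphable"):
            build_gene_graph("G", t)


class TestCommunities:
    def test_two_blocks_recovered_and_match_bruteforce(self):
        w = two_block_weights((3, 3), intra=0.9, inter=0.1)
        g = graph_from_weights(w)
        membership = detect_communities(g, seed=0)
        blocks = {frozenset(np.flatnonzero(np.array(membership) == c))
                  for c in set(membership)}
        assert blocks == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}
        best_q, _ = best_partition_oracle(w)
        assert partition_modularity(g, membership) == pytest.approx(best_q, abs=1e-12)

    def test_homogeneous_graph_single_community(self):
        w = np.full((6, 6), 0.5)
        g = graph_from_weights(w)
        assert len(set(detect_communities(g, seed=0))) == 1

    def test_near_disconnected_cliques_split(self):
        w = two_block_weights((4, 4), intra=0.95, inter=1e-6)
        assert len(set(detect_communities(graph_from_weights(w), seed=0))) == 2

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(5)
        w = rng.uniform(0.1, 1.0, (12, 12))
        w = (w + w.T) / 2
        g = graph_from_weights(w)
        assert detect_communities(g, seed=3) == detect_communities(g, seed=3)


class TestModularity:
    def test_single_community_is_zero(self):
        g = graph_from_weights(two_block_weights((3, 3)))
        assert partition_modularity(g, [0] * 6) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula(self):
        w = two_block_weights((3, 3), intra=0.9, inter=0.1)
        g = graph_from_weights(w)
        part = [0, 0, 0, 1, 1, 1]
        assert partition_modularity(g, part) == pytest.approx(
            modularity_oracle(w, [[0, 1, 2], [3, 4, 5]]), abs=1e-12
        )

    def test_all_singletons_negative_on_positive_weights(self):
        g = graph_from_weights(np.full((5, 5), 0.4))
        assert partition_modularity(g, list(range(5))) < 0

    def test_partition_must_cover_vertices(self):
        g = graph_from_weights(two_block_weights((3, 3)))
        with pytest.raises(ValueError):
            partition_modularity(g, [0, 0, 0])

    def test_leiden_attains_bruteforce_optimum_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for n in (4, 5, 6, 7):
            w = rng.uniform(0.05, 1.0, (n, n))
            w = (w + w.T) / 2
            g = graph_from_weights(w)
            membership = detect_communities(g, seed=1)
            best_q, _ = best_partition_oracle(w)
            assert partition_modularity(g, membership) >= best_q - 1e-12


class TestAssignment:
    def params(self):
        return DetectionParams()

    def test_small_gene_kept_as_single_unresolved_group(self):
        a = assign_proteoform_groups("NEK2", None, None, analyzed=False,
                                     peptide_ids=[f"p{i}" for i in range(9)])
        assert [pid for pid, _ in a.groups] == ["NEK2_0"]
        assert len(a.groups[0][1]) == 9
        assert not a.analyzed

    def test_communities_become_size_ordered_groups(self):
        # 12 peptides in communities of sizes 7 / 3 / 2 with clear structure
        w = two_block_weights((7, 3, 2), intra=0.95, inter=0.05)
        g = graph_from_weights(w)
        part = [0] * 7 + [1] * 3 + [2] * 2
        a = assign_proteoform_groups("G", g, part, analyzed=True)
        names = [pid for pid, _ in a.groups]
        sizes = [len(m) for _, m in a.groups]
        assert names == ["G_1", "G_2"]
        assert sizes == [7, 3]
        assert len(a.unassigned_peptides) == 2

    def test_low_modularity_collapses_to_single_group(self):
        w = np.full((12, 12), 0.5)
        g = graph_from_weights(w)
        a = assign_proteoform_groups("G", g, [0] * 12, analyzed=True)
        assert [pid for pid, _ in a.groups] == ["G_0"]

    def test_groups_and_unassigned_partition_all_peptides(self):
        w = two_block_weights((5, 4, 2), intra=0.9, inter=0.1)
        g = graph_from_weights(w)
        part = [0] * 5 + [1] * 4 + [2] * 2
        a = assign_proteoform_groups("G", g, part, analyzed=True)
        members = set().union(*(m for _, m in a.groups)) | set(a.unassigned_peptides)
        assert members == set(g.peptide_ids)
        for _, m1 in a.groups:
            for _, m2 in a.groups:
                assert m1 == m2 or not (m1 & m2)

    def test_tie_broken_by_smallest_member_peptide(self):
        w = two_block_weights((3, 3), intra=0.9, inter=0.1)
        g = graph_from_weights(w)
        a = assign_proteoform_groups("G", g, [1, 1, 1, 0, 0, 0], analyzed=True)
        # equal sizes: group containing the lexicographically smallest peptide first
        assert min(a.groups[0][1]) < min(a.groups[1][1])


class TestDetectEndToEnd:
    def test_perturbation_toward_other_community_never_raises_q(self, paper_temps):
        from meltforms.meltfit import sigmoid

        base_a = sigmoid(paper_temps, 50 * 48.0, 50.0, 0.0)
        base_b = sigmoid(paper_temps, 50 * 56.0, 50.0, 0.0)
        prev_q = np.inf
        for lam in (0.0, 0.3, 0.6, 0.9):
            blended = (1 - lam) * base_b + lam * base_a
            curves = {}
            for i in range(5):
                curves[f"a{i}"] = np.tile(base_a, (3, 1))
                curves[f"b{i}"] = np.tile(blended, (3, 1))
            t = make_gene_tensor(curves, paper_temps,
                                 cell_lines=["C1", "C2", "C3"])
            g = build_gene_graph("G", t)
            membership = detect_communities(g, seed=0)
            q = partition_modularity(g, membership)
            assert q <= prev_q + 1e-9
            prev_q = q

    def test_detect_proteoforms_deterministic(self, paper_temps):
        from meltforms.simulate import SimConfig, simulate_benchmark

        cfg = SimConfig(n_negative=6, n_positive=4, peptides_per_protein=12)
        t, _ = simulate_benchmark(cfg, seed=9)
        a1 = detect_proteoforms(t, seed=4)
        a2 = detect_proteoforms(t, seed=4)
        for gene in a1:
            assert a1[gene].groups == a2[gene].groups
            assert a1[gene].modularity_q == a2[gene].modularity_q


class TestSummarizeProfiles:
    def make_raw(self, intensities, ids=None):
        P = len(intensities)
        ids = ids or [f"P{i}" for i in range(P)]
        return PeptideQuantMatrix(
            ids, [frozenset({"G"})] * P,
            np.asarray(intensities, dtype=float)[:, np.newaxis, :],
            np.array([41.0, 50.0, 59.0]), ["A"],
        )

    def test_single_member_group_equals_peptide_profile(self):
        raw = self.make_raw([[200.0, 100.0, 50.0]])
        a = assign_proteoform_groups("G", None, None, analyzed=False,
                                     peptide_ids=["P0"])
        prof = summarize_proteoform_profiles({"G": a}, raw, normalize=False)
        assert np.allclose(prof.x[0, 0], [1.0, 0.5, 0.25])

    def test_group_reference_is_summed_raw_signal(self):
        raw = self.make_raw([[100.0, 50.0, 10.0], [300.0, 150.0, 30.0]])
        a = assign_proteoform_groups("G", None, None, analyzed=False,
                                     peptide_ids=["P0", "P1"])
        prof = summarize_proteoform_profiles({"G": a}, raw, normalize=False)
        assert prof.x[0, 0, 0] == 1.0  # reference 400 -> fold change 1

    def test_equal_reference_members_average_their_curves(self):
        # curves (1, .5) and (1, .3) with equal raw reference -> (1, .4)
        raw = self.make_raw([[100.0, 50.0, 40.0], [100.0, 30.0, 20.0]])
        a = assign_proteoform_groups("G", None, None, analyzed=False,
                                     peptide_ids=["P0", "P1"])
        prof = summarize_proteoform_profiles({"G": a}, raw, normalize=False)
        assert prof.x[0, 0, 1] == pytest.approx(0.4)

    def test_all_missing_channel_stays_masked(self):
        raw = self.make_raw([[100.0, np.nan, 10.0], [200.0, np.nan, 30.0]])
        a = assign_proteoform_groups("G", None, None, analyzed=False,
                                     peptide_ids=["P0", "P1"])
        prof = summarize_proteoform_profiles({"G": a}, raw, normalize=False)
        assert np.isnan(prof.x[0, 0, 1])
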