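import numpy as np
import pytest
from scipy.stats import spearmanr

from pseudopath import (
    PseudotimeVector,
    build_reference_path,
    embed_transitions,
    merge_paths,
    transition_matrix,
)
from pseudopath.hampath import HamiltonianPath


class TestBuildReferencePath:
    def test_identical_vectors_recovered(self):
        v = np.array([0.1, 0.4, 0.2, 0.9, 0.6])
        res = build_reference_path([v] * 5)
        expected = (v - v.min()) / (v.max() - v.min())
        np.testing.assert_allclose(res.pseudotime.scores, expected)
        assert res.best_score == pytest.approx(10.0)

    def test_reflection_is_undone(self):
        v = np.linspace(0, 1, 8)
        vecs = [v, v, 1.0 - v, v, v]
        res = build_reference_path(vecs)
        np.testing.assert_allclose(res.pseudotime.scores, v, atol=1e-12)

    def test_orientation_search_counters(self):
        vecs = [np.random.default_rng(s).uniform(size=10) for s in range(5)]
        res = build_reference_path(vecs)
        assert res.n_assignments_evaluated == 2**5 == 32
        assert res.n_pairwise_scores == 10

    def test_noisy_monotone_averaging_beats_individuals(self):
        rng = np.random.default_rng(7)
        clean = np.linspace(0, 1, 60)
        vecs = [clean + rng.normal(0, 0.05, size=60) for _ in range(5)]
        res = build_reference_path(vecs)
        merged_rho = spearmanr(res.pseudotime.scores, clean).statistic
        individual = [spearmanr(v, clean).statistic for v in vecs]
        assert merged_rho >= max(individual) - 1e-12

    def test_constant_vector_is_orientation_neutral(self):
        v = np.linspace(0, 1, 6)
        res = build_reference_path([v, v, np.full(6, 0.5), v, v])
        assert np.isfinite(res.pseudotime.scores).all()


class TestMergePaths:
    def test_self_merge_is_idempotent(self):
        v = np.linspace(0, 1, 10)
        ref = PseudotimeVector(v)
        merged = merge_paths(ref, [v, v, v])
        np.testing.assert_allclose(merged.scores, v, atol=1e-12)

    def test_reflected_input_is_flipped_before_merge(self):
        v = np.linspace(0, 1, 10)
        merged = merge_paths(PseudotimeVector(v), [1.0 - v])
        np.testing.assert_allclose(merged.scores, v, atol=1e-12)

    def test_final_scaling_spans_unit_interval(self):
        rng = np.random.default_rng(0)
        ref = PseudotimeVector(rng.uniform(size=20))
        merged = merge_paths(ref, [rng.uniform(size=20) for _ in range(4)])
        assert merged.scores.min() == 0.0
        assert merged.scores.max() == 1.0

    def test_invariant_to_reversing_input_subsets(self):
        # reference building + merging must undo arbitrary per-path reversals,
        # up to one global reflection
        rng = np.random.default_rng(4)
        clean = np.linspace(0, 1, 30)
        vecs = [clean + rng.normal(0, 0.03, 30) for _ in range(8)]
        def pipeline(vs):
            ref = build_reference_path(vs[:5])
            return merge_paths(ref.pseudotime, vs[5:]).scores
        base = pipeline(vecs)
        flip_mask = rng.integers(0, 2, size=8).astype(bool)
        flipped = [1.0 - v if f else v for v, f in zip(vecs, flip_mask)]
        alt = pipeline(flipped)
        agree = np.allclose(alt, base, atol=1e-9)
        agree_reflected = np.allclose(1.0 - alt, base, atol=1e-9)
        assert agree or agree_reflected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            merge_paths(PseudotimeVector(np.zeros(3)), [np.zeros(4)])


class TestTransitionMatrix:
    def test_single_path_worked_example(self):
        # solution 2-3-1 (1-based) adds unit mass at (2,3) and (3,1)
        path = HamiltonianPath(np.array([1, 2, 0]), 0.0)  # 0-based
        t = transition_matrix([path], n_cells=3)
        expected = np.zeros((3, 3))
        expected[1, 2] = 1.0
        expected[2, 0] = 1.0
        np.testing.assert_array_equal(t, expected)

    def test_additivity(self):
        path = HamiltonianPath(np.array([1, 2, 0]), 0.0)
        t1 = transition_matrix([path], n_cells=3)
        t2 = transition_matrix([path, path], n_cells=3)
        np.testing.assert_array_equal(t2, 2 * t1)

    def test_total_mass_equals_paths_times_edges(self):
        n, p = 8, 5
        rng = np.random.default_rng(2)
        paths = [HamiltonianPath(rng.permutation(n), 0.0) for _ in range(p)]
        t = transition_matrix(paths, n_cells=n)
        assert t.sum() == pytest.approx(p * (n - 1))

    def test_cluster_paths_split_mass_uniformly(self):
        from pseudopath import ClusterAssignment

        labels = np.array([0, 0, 1, 1, 1])
        assign = ClusterAssignment(2, labels, np.zeros((2, 2)))
        path = HamiltonianPath(np.array([0, 1]), 0.0)
        t = transition_matrix([path], [assign])
        # one unit of mass split over 2x3 member pairs
        assert t.sum() == pytest.approx(1.0)
        assert t[0, 2] == pytest.approx(1 / 6)
        assert t[2, 0] == 0.0


class TestEmbedTransitions:
    def test_linear_consensus_pc1_tracks_chain_order(self):
        # cluster-level paths at every granularity over a common linear
        # order give a multi-width band matrix whose leading component
        # follows the chain
        from pseudopath import ClusterAssignment

        n = 20
        paths, assigns = [], []
        for k in range(3, n + 1):
            labels = (np.arange(n) * k) // n
            assigns.append(ClusterAssignment(k, labels, np.zeros((k, 2))))
            paths.append(HamiltonianPath(np.arange(k), 0.0))
        t = transition_matrix(paths, assigns)
        coords = embed_transitions(t, n_components=2, row_normalize=True)
        rho = abs(spearmanr(coords[:, 0], np.arange(n)).statistic)
        assert rho >= 0.9

    def test_minimal_three_cells(self):
        t = transition_matrix([HamiltonianPath(np.array([0, 1, 2]), 0.0)], n_cells=3)
        coords = embed_transitions(t, n_components=2)
        assert coords.shape == (3, 2)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="no transitions"):
            embed_transitions(np.zeros((5, 5)))

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(6)
        paths = [HamiltonianPath(rng.permutation(10), 0.0) for _ in range(4)]
        t = transition_matrix(paths, n_cells=10)
        c1 = embed_transitions(t)
        c2 = embed_transitions(t)
        np.testing.assert_array_equal(c1, c2)
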