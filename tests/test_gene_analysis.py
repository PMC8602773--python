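import itertools

import numpy as np
import pytest
from scipy.stats import norm

from pseudopath import (
    ExpressionMatrix,
    distance_correlation,
    fit_gene_hmm,
    mic_score,
    order_gene_modules,
    rank_genes,
)
from pseudopath.gene_analysis import GeneStateTrack, state_matrix


def dcor_direct_summation(x, y):
    """Independent O(n^2) oracle using the raw moment formula
    dCov^2 = S1 + S2 - 2*S3, without forming centered matrices."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    ax = np.abs(x[:, None] - x[None, :])
    ay = np.abs(y[:, None] - y[None, :])

    def dcov2(a, b):
        s1 = (a * b).sum() / n**2
        s2 = a.sum() / n**2 * b.sum() / n**2
        s3 = (a.sum(axis=1) @ b.sum(axis=1)) / n**3
        return s1 + s2 - 2 * s3

    v = dcov2(ax, ay)
    vx = dcov2(ax, ax)
    vy = dcov2(ay, ay)
    if vx * vy <= 0:
        return 0.0
    return float(np.sqrt(max(v, 0.0) / np.sqrt(vx * vy)))


def map_path_by_enumeration(obs, track: GeneStateTrack):
    """Exhaustive MAP state path under the fitted model (2^L paths)."""
    k = len(track.means)
    log_start = np.log(track.startprob)
    log_trans = np.log(track.transition)
    log_emit = np.array(
        [norm.logpdf(obs, track.means[s], track.sds[s]) for s in range(k)]
    )
    best, best_lp = None, -np.inf
    for path in itertools.product(range(k), repeat=len(obs)):
        lp = log_start[path[0]] + log_emit[path[0], 0]
        for t in range(1, len(obs)):
            lp += log_trans[path[t - 1], path[t]] + log_emit[path[t], t]
        if lp > best_lp:
            best_lp, best = lp, path
    return np.array(best)


class TestDistanceCorrelation:
    def test_self_dependence_is_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert distance_correlation(x, x) == pytest.approx(1.0)

    def test_linear_negative_map_is_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 7.0])
        assert distance_correlation(x, -x) == pytest.approx(1.0)

    def test_matches_direct_summation_oracle(self):
        cases = [
            (np.array([1.0, 2.0, 3.0, 4.0]), np.array([1.0, 3.0, 2.0, 4.0])),
        ]
        rng = np.random.default_rng(12)
        for n in (10, 25, 50):
            cases.append((rng.normal(size=n), rng.normal(size=n)))
            z = rng.uniform(size=n)
            cases.append((z, np.sin(6 * z) + rng.normal(0, 0.1, n)))
        for x, y in cases:
            assert distance_correlation(x, y) == pytest.approx(
                dcor_direct_summation(x, y), abs=1e-10
            )

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert distance_correlation(x, y) == pytest.approx(
            distance_correlation(y, x), abs=1e-12
        )

    def test_constant_vector_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert distance_correlation(np.ones(5), np.arange(5.0)) == 0.0


class TestMicScore:
    def test_noiseless_monotone_is_one(self):
        x = np.linspace(0, 1, 100)
        assert mic_score(x, x**3 + 2) == pytest.approx(1.0, abs=1e-6)

    def test_identity_is_one(self):
        x = np.arange(50.0)
        assert mic_score(x, x) == pytest.approx(1.0, abs=1e-6)

    def test_independent_null_stays_low(self):
        vals = []
        for s in range(20):
            rng = np.random.default_rng(s)
            vals.append(mic_score(rng.uniform(size=200), rng.uniform(size=200)))
        assert np.mean(vals) < 0.3

    def test_symmetric_and_monotone_invariant(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(size=80)
        y = np.sin(4 * x) + rng.normal(0, 0.05, 80)
        assert mic_score(x, y) == pytest.approx(mic_score(y, x), abs=1e-12)
        # strictly increasing transforms preserve equal-frequency bins
        assert mic_score(np.exp(x), y**3 if (y > 0).all() else y) == pytest.approx(
            mic_score(x, y), abs=1e-12
        )

    def test_constant_vector_zero(self):
        assert mic_score(np.ones(20), np.arange(20.0)) == 0.0


class TestRankGenes:
    def _expr(self, columns, ids):
        vals = np.column_stack(columns)
        return ExpressionMatrix(vals, [f"c{i}" for i in range(vals.shape[0])], ids)

    def test_gene_equal_to_pseudotime_is_kept_with_unit_scores(self):
        pt = np.linspace(0, 1, 60)
        rng = np.random.default_rng(1)
        expr = self._expr([pt, rng.permutation(pt)], ["match", "shuffled"])
        scores = rank_genes(expr, pt)
        top = scores[0]
        assert top.gene_id == "match"
        assert top.dcor == pytest.approx(1.0)
        assert top.mic == pytest.approx(1.0, abs=1e-6)
        assert top.kept

    def test_independent_gene_dropped_at_half(self):
        rng = np.random.default_rng(9)
        pt = np.linspace(0, 1, 200)
        expr = self._expr([rng.permutation(pt)], ["null"])
        scores = rank_genes(expr, pt)
        assert not scores[0].kept

    def test_zero_threshold_keeps_all(self):
        rng = np.random.default_rng(4)
        pt = np.linspace(0, 1, 30)
        expr = self._expr([rng.uniform(size=30) for _ in range(3)], ["a", "b", "c"])
        assert all(g.kept for g in rank_genes(expr, pt, threshold=0.0))


class TestFitGeneHmm:
    def test_step_sequence_decodes_to_two_blocks(self):
        v = np.array([0, 0, 0, 0, 10, 10, 10, 10], float)
        track = fit_gene_hmm(v)
        assert track.states.tolist() == [0, 0, 0, 0, 1, 1, 1, 1]
        assert track.means[1] > track.means[0]

    def test_constant_sequence_degenerate_single_state(self):
        track = fit_gene_hmm(np.full(6, 3.0))
        assert track.degenerate
        assert track.states.tolist() == [0] * 6

    def test_transition_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        track = fit_gene_hmm(rng.normal(size=30))
        np.testing.assert_allclose(track.transition.sum(axis=1), 1.0, atol=1e-10)

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_viterbi_matches_exhaustive_map_enumeration(self, seed):
        # length-12 sequences from a known 2-state generator: the decoded
        # path must equal the MAP path under the *fitted* parameters
        rng = np.random.default_rng(seed)
        states = [0]
        for _ in range(11):
            states.append(states[-1] if rng.random() < 0.9 else 1 - states[-1])
        obs = np.array([rng.normal(0.0 if s == 0 else 5.0, 1.0) for s in states])
        track = fit_gene_hmm(obs)
        oracle = map_path_by_enumeration(obs, track)
        assert track.states.tolist() == oracle.tolist()

    def test_three_state_mode(self):
        v = np.concatenate([np.zeros(5), np.full(5, 5.0), np.full(5, 10.0)])
        track = fit_gene_hmm(v + np.random.default_rng(0).normal(0, 0.1, 15),
                             n_states=3)
        assert set(track.states) == {0, 1, 2}
        assert np.all(np.diff(track.means) > 0)


class TestOrderGeneModules:
    def _track(self, states, gid):
        k = int(np.max(states)) + 1 if np.max(states) > 0 else 1
        return GeneStateTrack(gid, np.asarray(states, int), np.arange(k, dtype=float),
                              np.ones(k), np.eye(k))

    def test_identical_tracks_share_module(self):
        t1 = self._track([0, 0, 1, 1], "a")
        t2 = self._track([0, 0, 1, 1], "b")
        order, modules = order_gene_modules([t1, t2])
        assert modules[0] == modules[1]
        assert sorted(order) == [0, 1]

    def test_complementary_tracks_split(self):
        t1 = self._track([0, 0, 1, 1], "a")
        t2 = self._track([1, 1, 0, 0], "b")
        _, modules = order_gene_modules([t1, t2], cut_height=0.9)
        assert modules[0] != modules[1]

    def test_three_blocks_recovered(self):
        rng = np.random.default_rng(5)
        blocks = [rng.integers(0, 2, size=30) for _ in range(3)]
        tracks = []
        for b, base in enumerate(blocks):
            for i in range(10):
                tracks.append(self._track(base, f"g{b}_{i}"))
        _, modules = order_gene_modules(tracks, n_modules=3)
        for b in range(3):
            assert len({modules[b * 10 + i] for i in range(10)}) == 1
        assert len(set(modules)) == 3

    def test_state_matrix_shape(self):
        tracks = [self._track([0, 1, 0], "a"), self._track([1, 1, 1], "b")]
        assert state_matrix(tracks).shape == (2, 3)
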