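"""Agreement metrics: label alignment, kappa, centrality, RMSIP."""

import itertools

import numpy as np
import pytest

from dyncomm.communities import CommunityPartition, DistanceCorrelationMatrix
from dyncomm.enm import CorrelationMatrix
from dyncomm.errors import InputError
from dyncomm.metrics import (
    align_labels,
    centrality_correlation,
    closeness_centrality,
    cohens_kappa,
    compare_correlations,
    kappa_profile,
    rmsip,
)
from dyncomm.synthetic import make_block_dcc
from .oracles import floyd_warshall_closeness


def part(labels):
    labels = np.asarray(labels, dtype=int)
    return CommunityPartition(labels=labels, n_c=len(np.unique(labels)))


class TestAlignLabels:
    def test_pure_swap(self):
        b = align_labels(part([1, 1, 2, 2]), part([2, 2, 1, 1]))
        assert b.labels.tolist() == [1, 1, 2, 2]

    def test_identity(self):
        b = align_labels(part([1, 1, 2, 2]), part([1, 1, 2, 2]))
        assert b.labels.tolist() == [1, 1, 2, 2]

    def test_three_way_matches_brute_force(self):
        a = part([1, 1, 2, 2, 3])
        b = part([3, 3, 1, 1, 2])
        aligned = align_labels(a, b)
        assert aligned.labels.tolist() == [1, 1, 2, 2, 3]
        # brute force over all 3! permutations confirms optimality
        best = max(
            sum(pa == perm[pb - 1] for pa, pb in zip(a.labels, b.labels))
            for perm in itertools.permutations([1, 2, 3])
        )
        assert np.sum(a.labels == aligned.labels) == best

    def test_mismatched_sets_rejected(self):
        with pytest.raises(InputError):
            align_labels(part([1, 2]), part([1, 2, 2]))


class TestCohensKappa:
    def test_identical_partitions(self):
        assert cohens_kappa(part([1, 1, 2, 2]), part([1, 1, 2, 2])) == 1.0

    def test_worked_example(self):
        # p_o = 0.75, p_e = 0.5*0.25 + 0.5*0.75 = 0.5 -> K = 0.5
        assert cohens_kappa(part([1, 1, 2, 2]), part([1, 2, 2, 2])) == 0.5

    def test_unaligned_swap_gives_minus_one(self):
        """Why alignment is mandatory: a pure label swap scores K = -1."""
        assert cohens_kappa(part([1, 1, 2, 2]), part([2, 2, 1, 1])) == -1.0

    def test_invariant_to_label_permutation_after_alignment(self):
        rng = np.random.default_rng(9)
        a = part(rng.integers(1, 5, size=40))
        b_labels = rng.integers(1, 5, size=40)
        b = part(b_labels)
        k0 = cohens_kappa(a, align_labels(a, b))
        for perm in itertools.permutations([1, 2, 3, 4]):
            bp = part(np.array([perm[l - 1] for l in b_labels]))
            assert np.isclose(cohens_kappa(a, align_labels(a, bp)), k0)

    def test_random_partitions_center_on_zero(self):
        """Unaligned kappa of independent partitions has mean ~ 0."""
        rng = np.random.default_rng(2024)
        vals = []
        for _ in range(1000):
            a = part(np.concatenate([np.arange(1, 5),
                                     rng.integers(1, 5, size=196)]))
            b = part(np.concatenate([np.arange(1, 5),
                                     rng.integers(1, 5, size=196)]))
            vals.append(cohens_kappa(a, b))
        assert abs(np.mean(vals)) < 0.02

    def test_degenerate_single_category(self):
        a = CommunityPartition(labels=np.ones(5, dtype=int), n_c=1)
        b = CommunityPartition(labels=np.ones(5, dtype=int), n_c=1)
        assert cohens_kappa(a, b) == 1.0


class TestKappaProfile:
    def test_self_comparison_is_perfect(self):
        c, _ = make_block_dcc([4, 4, 4], noise_sd=0.05, seed=1)
        profile, kmax, best_nc = kappa_profile(c, c)
        assert all(v == 1.0 for v in profile.values())
        assert kmax == 1.0 and best_nc == 2  # smallest N_c on ties

    def test_shared_blocks_with_independent_noise(self):
        a, _ = make_block_dcc([4, 4, 4], noise_sd=0.05, seed=10)
        b, _ = make_block_dcc([4, 4, 4], noise_sd=0.05, seed=11)
        profile, _, _ = kappa_profile(a, b)
        assert profile[3] > 0.8


class TestClosenessCentrality:
    def test_uniform_triangle(self):
        d = DistanceCorrelationMatrix(
            matrix=np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
        )
        assert np.allclose(closeness_centrality(d), [1.0, 1.0, 1.0])

    def test_indirect_path_wins(self):
        # 1 -> 3 via node 2 costs 0.2 < 0.9 direct
        d = DistanceCorrelationMatrix(
            matrix=np.array([[0, 0.1, 0.9], [0.1, 0, 0.1], [0.9, 0.1, 0]])
        )
        cent = closeness_centrality(d)
        assert np.isclose(cent[1], 1 / 0.2)
        assert np.isclose(cent[0], 1 / 0.3)

    def test_zero_farness_flagged_infinite(self):
        d = DistanceCorrelationMatrix(matrix=np.zeros((3, 3)))
        with pytest.warns(UserWarning, match="zero"):
            cent = closeness_centrality(d)
        assert np.all(np.isinf(cent))

    def test_matches_floyd_warshall_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            n = int(rng.integers(3, 16))
            w = rng.uniform(0.05, 2.0, size=(n, n))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0.0)
            ours = closeness_centrality(DistanceCorrelationMatrix(matrix=w))
            assert np.allclose(ours, floyd_warshall_closeness(w), atol=1e-12)


class TestCentralityCorrelation:
    def test_affine_relation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert np.isclose(centrality_correlation(x, 2 * x + 1), 1.0)

    def test_negation(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        assert np.isclose(centrality_correlation(x, -x), -1.0)

    def test_outlier_example(self):
        r = centrality_correlation(np.array([1.0, 2, 3, 4]),
                                   np.array([1.0, 2, 3, 100]))
        assert np.isclose(r, 0.78503, atol=1e-5)

    def test_spearman_option(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([1.0, 2, 3, 100])  # monotone, so rank-perfect
        assert np.isclose(centrality_correlation(x, y, method="spearman"), 1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(InputError):
            centrality_correlation(np.ones(4), np.arange(4.0))


class TestRmsip:
    def test_self_overlap_is_one(self):
        c, _ = make_block_dcc([5, 5], noise_sd=0.02, seed=3)
        for n in (1, 3, 5):
            assert np.isclose(rmsip(c, c, n), 1.0, atol=1e-10)

    def test_orthogonal_subspaces_are_zero(self):
        a = np.diag([10.0, 1.0, 0.5, 0.2])
        b = np.diag([1.0, 10.0, 0.5, 0.2])
        assert np.isclose(rmsip(a, b, 1), 0.0, atol=1e-10)

    def test_rotated_basis_same_subspace(self):
        """A 45-degree rotation within the top-2 span leaves RMSIP at 1."""
        a = np.diag([10.0, 9.0, 1.0, 0.5])
        q = np.eye(4)
        s = 1 / np.sqrt(2)
        q[:2, :2] = [[s, s], [s, -s]]
        b = q @ a @ q.T
        assert np.isclose(rmsip(a, b, 2), 1.0, atol=1e-10)

    def test_monotone_under_orthogonal_noise(self):
        """Mixing an orthogonal direction into a subspace lowers RMSIP."""
        a = np.diag([10.0, 9.0, 1.0, 0.5])
        vals = []
        for t in (0.0, 0.3, 0.6):
            q = np.eye(4)
            c, s = np.cos(t), np.sin(t)
            q[1, 1], q[1, 2], q[2, 1], q[2, 2] = c, -s, s, c
            vals.append(rmsip(a, q @ a @ q.T, 2))
        assert vals[0] >= vals[1] >= vals[2]
        assert vals[2] < vals[0]

    def test_n_out_of_range(self):
        a = np.eye(3)
        with pytest.raises(InputError):
            rmsip(a, a, 4)


def test_compare_correlations_full_report():
    a, _ = make_block_dcc([6, 6], noise_sd=0.03, seed=21)
    b, _ = make_block_dcc([6, 6], noise_sd=0.03, seed=22)
    rep = compare_correlations(a, b, n_rmsip=3)
    assert -1.0 <= rep.kappa_max <= 1.0
    assert rep.kappa_max == max(rep.kappa_by_nc.values())
    assert 0.0 <= rep.rmsip <= 1.0
    assert rep.kappa_by_nc[2] == 1.0  # blocks dominate the noise
    d = rep.to_dict()
    assert set(d) >= {"kappa_by_nc", "kappa_max", "centrality_correlation",
                      "rmsip"}
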