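"""Agglomerative clustering, medoid centers, and ensemble reduction."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from abensemble.cluster import (
    DistanceMatrix,
    agglomerative_cluster,
    reduce_ensemble,
    sweep_reduction,
)
from abensemble.errors import ValidationError
from abensemble.fixtures import FixtureSpec, make_planted_ensemble, make_toy_chain
from oracles import medoid_by_enumeration, naive_agglomerative


def random_distance_matrix(rng, n):
    m = rng.uniform(0.1, 10.0, size=(n, n))
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix(labels=[f"m{i}" for i in range(n)], values=m)


def partition_of(assignment):
    clusters = {}
    for label, ci in assignment.membership.items():
        clusters.setdefault(ci, set()).add(int(label[1:]))
    return {frozenset(v) for v in clusters.values()}


class TestAgglomerativeCluster:
    def test_hand_worked_1d_example(self):
        """Points {0, 1, 10, 11} split into {0,1} and {10,11} at k=2."""
        pts = np.array([0.0, 1.0, 10.0, 11.0])
        values = np.abs(pts[:, None] - pts[None, :])
        dist = DistanceMatrix(labels=["m0", "m1", "m2", "m3"], values=values)
        a = agglomerative_cluster(dist, k=2, linkage="complete")
        assert partition_of(a) == {frozenset({0, 1}), frozenset({2, 3})}

    def test_k_equals_n_gives_singletons(self, rng):
        dist = random_distance_matrix(rng, 6)
        a = agglomerative_cluster(dist, k=6, linkage="average")
        assert sorted(a.sizes()) == [1] * 6

    def test_k_equals_1_gives_one_cluster(self, rng):
        dist = random_distance_matrix(rng, 6)
        a = agglomerative_cluster(dist, k=1, linkage="single")
        assert a.sizes() == [6]

    @pytest.mark.parametrize("linkage", ["single", "average", "complete"])
    def test_matches_naive_reference_on_random_matrices(self, linkage):
        """Partitions equal an O(N^3) from-scratch agglomeration, all K, N<=12."""
        rng = np.random.default_rng(2024)
        for _ in range(25):
            n = int(rng.integers(4, 13))
            dist = random_distance_matrix(rng, n)
            for k in range(1, n + 1):
                ours = partition_of(agglomerative_cluster(dist, k=k, linkage=linkage))
                ref = naive_agglomerative(dist.values, k, linkage)
                assert ours == ref, f"n={n} k={k} {linkage}"

    @pytest.mark.parametrize("linkage", ["single", "average", "complete"])
    def test_matches_scipy_hierarchy(self, linkage):
        """Cross-check against scipy's linkage/cut_tree on tie-free matrices."""
        from scipy.cluster.hierarchy import cut_tree, linkage as scipy_linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(77)
        for _ in range(10):
            n = int(rng.integers(5, 15))
            dist = random_distance_matrix(rng, n)
            Z = scipy_linkage(squareform(dist.values, checks=False), method=linkage)
            for k in (1, 2, n // 2, n):
                ours = agglomerative_cluster(dist, k=k, linkage=linkage)
                labels = cut_tree(Z, n_clusters=k).ravel()
                ours_labels = [ours.membership[f"m{i}"] for i in range(n)]
                assert adjusted_rand_score(labels, ours_labels) == pytest.approx(1.0)

    def test_deterministic_across_runs(self, rng):
        dist = random_distance_matrix(rng, 10)
        a = agglomerative_cluster(dist, k=3, linkage="complete")
        b = agglomerative_cluster(dist, k=3, linkage="complete")
        assert a.membership == b.membership and a.centers == b.centers

    def test_k_out_of_range(self, rng):
        dist = random_distance_matrix(rng, 4)
        with pytest.raises(ValueError):
            agglomerative_cluster(dist, k=0)
        with pytest.raises(ValueError):
            agglomerative_cluster(dist, k=5)

    def test_asymmetric_matrix_rejected(self):
        values = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValidationError):
            DistanceMatrix(labels=["a", "b"], values=values)


class TestClusterCenters:
    def test_singleton_cluster_returns_its_member(self, rng):
        dist = random_distance_matrix(rng, 3)
        a = agglomerative_cluster(dist, k=3, linkage="complete")
        assert set(a.centers.values()) == {"m0", "m1", "m2"}

    def test_medoid_by_sum_of_distances(self):
        # d(a,b)=1, d(a,c)=1, d(b,c)=2 -> medoid a
        values = np.array([[0.0, 1, 1], [1, 0, 2], [1, 2, 0]])
        dist = DistanceMatrix(labels=["a", "b", "c"], values=values)
        a = agglomerative_cluster(dist, k=1, linkage="complete")
        assert a.centers[0] == "a"

    def test_tie_goes_to_earliest_member(self):
        values = np.array([[0.0, 1, 2], [1, 0, 1], [2, 1, 0]])
        # symmetric chain: a and c tie? sums: a=3, b=2, c=3 -> b; force a tie:
        values = np.array([[0.0, 1, 1], [1, 0, 1], [1, 1, 0]])
        dist = DistanceMatrix(labels=["a", "b", "c"], values=values)
        a = agglomerative_cluster(dist, k=1, linkage="complete")
        assert a.centers[0] == "a"

    def test_matches_enumeration_oracle(self, rng):
        dist = random_distance_matrix(rng, 12)
        a = agglomerative_cluster(dist, k=3, linkage="average")
        for ci in range(3):
            members = [int(m[1:]) for m in a.members_of(ci)]
            expected = medoid_by_enumeration(dist.values, sorted(members))
            assert a.centers[ci] == f"m{expected}"


class TestReduceEnsemble:
    def test_recovers_planted_partition(self, three_cluster_ensemble):
        ens, truth, regions = three_cluster_ensemble
        _, assignment = reduce_ensemble(
            ens, regions, k=3, linkage="complete", return_assignment=True
        )
        predicted = [assignment.membership[lab] for lab in ens.labels]
        assert adjusted_rand_score(truth, predicted) == pytest.approx(1.0)

    def test_k_equals_size_returns_same_members(self, three_cluster_ensemble):
        ens, _, regions = three_cluster_ensemble
        sub = ens.subset(range(6))
        reduced = reduce_ensemble(sub, regions, k=6)
        assert sorted(reduced.labels) == sorted(sub.labels)

    def test_hundred_to_twenty_reduction(self):
        """Default operating point: 100 models in, exactly 20 centers out."""
        spec = FixtureSpec(
            seed=11, n_conformations=5, members_per_conformation=(20,) * 5,
            intra_noise_sigma=0.15, inter_conformation_shift=5.0,
        )
        planted = make_planted_ensemble(spec)
        reduced = reduce_ensemble(planted.ensemble, planted.regions, k=20)
        assert len(reduced) == 20

    def test_k_larger_than_ensemble_rejected(self, three_cluster_ensemble):
        ens, _, regions = three_cluster_ensemble
        with pytest.raises(ValueError):
            reduce_ensemble(ens.subset(range(4)), regions, k=5)


@pytest.fixture(scope="module")
def sweep_table():
    spec = FixtureSpec(
        seed=13, n_conformations=4, members_per_conformation=(6,) * 4,
        intra_noise_sigma=0.2, inter_conformation_shift=4.0,
    )
    planted = make_planted_ensemble(spec)
    reference, _ = make_toy_chain(spec, conformation_id=0, member_index=900)
    return sweep_reduction(
        planted.ensemble, planted.regions, "H3",
        n_values=[1, 8, 16, 24], k_values=[1, 2, 4, 8, 16, 24],
        linkages=["single", "average", "complete"], reference=reference,
    )


class TestSweepReduction:
    def test_k_equals_n_recovers_all_column(self, sweep_table):
        rows = sweep_table[sweep_table.k == sweep_table.n]
        assert np.allclose(rows.best_center_rmsd, rows.all_min_rmsd, atol=1e-9)

    def test_monotone_non_increasing_in_k(self, sweep_table):
        for (n, linkage), group in sweep_table.groupby(["n", "linkage"]):
            vals = group.sort_values("k").best_center_rmsd.to_numpy()
            assert np.all(np.diff(vals) <= 1e-9), (n, linkage, vals)

    def test_best_center_never_beats_ensemble_minimum(self, sweep_table):
        assert (sweep_table.best_center_rmsd >= sweep_table.all_min_rmsd - 1e-9).all()

    def test_n_equals_1_trivial(self, sweep_table):
        row = sweep_table[(sweep_table.n == 1) & (sweep_table.k == 1)].iloc[0]
        assert row.best_center_rmsd == pytest.approx(row.all_min_rmsd)
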