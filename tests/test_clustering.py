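import numpy as np
import pytest

from modminer.ccrs import DistanceMatrix
from modminer.clustering import (
    ClusteringParams,
    auto_parameters,
    cluster_modules,
)

from oracles import density_cluster_bruteforce


def dmatrix(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"g{i:02d}" for i in range(len(values))]
    return DistanceMatrix(ids, values, np.isnan(values))


def block_matrix(sizes, within, between, jitter=0.0, rng=None):
    """Distance matrix of tight blocks: `within` inside, `between` across."""
    n = sum(sizes)
    values = np.full((n, n), float(between))
    start = 0
    for size in sizes:
        values[start:start + size, start:start + size] = within
        start += size
    if jitter and rng is not None:
        noise = rng.uniform(0, jitter, size=(n, n))
        noise = (noise + noise.T) / 2
        values += noise
    np.fill_diagonal(values, 0.0)
    return dmatrix(values)


class TestAutoParameters:
    def test_min_pts_follows_log_rule(self, rng):
        for n, expected in ((10, 3), (100, 5), (8, 3), (5, 2)):
            vals = rng.uniform(1, 2, size=(n, n))
            vals = (vals + vals.T) / 2
            np.fill_diagonal(vals, 0)
            params = auto_parameters(dmatrix(vals))
            assert params.min_pts == expected

    def test_eps_lands_between_separated_scales(self):
        # two tight blocks, within-distance 1, between-distance 10: any knee
        # method must place eps strictly between the scales
        D = block_matrix([6, 2], within=1.0, between=10.0)
        params = auto_parameters(D)
        assert 1.0 < params.eps < 10.0

    def test_auto_parameters_recover_planted_blocks(self, rng):
        D = block_matrix([7, 6, 5], within=1.0, between=9.0, jitter=0.3, rng=rng)
        params = auto_parameters(D)
        labels = cluster_modules(D, params).labels
        sizes = sorted(np.bincount(labels[labels >= 0]).tolist())
        assert sizes == [5, 6, 7]
        assert (labels >= 0).all()
        # the planted blocks are contiguous index ranges
        assert len(set(labels[:7])) == 1
        assert len(set(labels[7:13])) == 1
        assert len(set(labels[13:])) == 1

    def test_too_few_genes_rejected(self):
        D = block_matrix([4], within=1.0, between=2.0)
        with pytest.raises(ValueError, match="at least 5"):
            auto_parameters(D)

    def test_all_masked_rejected(self):
        values = np.full((6, 6), np.nan)
        np.fill_diagonal(values, 0.0)
        with pytest.raises(ValueError, match="masked"):
            auto_parameters(dmatrix(values))


class TestClusterModules:
    def test_fully_dense_matrix_is_one_all_core_cluster(self):
        D = block_matrix([8], within=1.0, between=1.0)
        out = cluster_modules(D, ClusteringParams(eps=1.5, min_pts=3))
        assert set(out.labels) == {0}
        assert all(t == "core" for t in out.point_types)

    def test_no_neighbors_is_all_noise(self):
        D = block_matrix([8], within=5.0, between=5.0)
        out = cluster_modules(D, ClusteringParams(eps=1.0, min_pts=2))
        assert all(l == -1 for l in out.labels)
        assert all(t == "noise" for t in out.point_types)

    def test_hand_built_two_blocks_and_isolate(self):
        # 9 points: two density blocks (4+4) and one isolated point
        D = block_matrix([4, 4, 1], within=1.0, between=8.0)
        params = ClusteringParams(eps=2.0, min_pts=2)
        out = cluster_modules(D, params)
        oracle_labels, oracle_types = density_cluster_bruteforce(
            D.values, D.key_gene_ids, params.eps, params.min_pts)
        assert out.labels.tolist() == oracle_labels
        assert out.point_types == oracle_types
        assert out.labels[-1] == -1 and out.point_types[-1] == "noise"
        assert out.n_modules == 2

    def test_border_point_attaches_to_nearest_core(self):
        # two 4-point cores with a point within eps of both; nearer core wins
        values = np.full((9, 9), 10.0)
        values[:4, :4] = 1.0
        values[4:8, 4:8] = 1.0
        values[8, 0] = values[0, 8] = 1.6
        values[8, 4] = values[4, 8] = 1.4
        np.fill_diagonal(values, 0.0)
        out = cluster_modules(dmatrix(values), ClusteringParams(eps=2.0, min_pts=2))
        assert out.point_types[8] == "border"
        assert out.labels[8] == out.labels[4]

    def test_partition_covers_every_gene(self, rng):
        vals = rng.uniform(0.5, 4, size=(20, 20))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        out = cluster_modules(dmatrix(vals), ClusteringParams(eps=1.5, min_pts=3))
        assert len(out.labels) == 20
        assert all(l == -1 or l >= 0 for l in out.labels)

    def test_masked_distances_become_noise(self):
        values = np.array([
            [0.0, 1.0, np.nan],
            [1.0, 0.0, np.nan],
            [np.nan, np.nan, 0.0],
        ])
        out = cluster_modules(dmatrix(values), ClusteringParams(eps=2.0, min_pts=1))
        assert out.labels[2] == -1

    def test_asymmetric_matrix_rejected(self):
        values = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            cluster_modules(dmatrix(values), ClusteringParams(eps=1.0, min_pts=1))

    def test_matches_closure_oracle_on_random_matrices(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 30))
            vals = rng.uniform(0.2, 3.0, size=(n, n))
            vals = (vals + vals.T) / 2
            if rng.random() < 0.3:  # sprinkle masked entries symmetrically
                mask = rng.random((n, n)) < 0.1
                mask |= mask.T
                vals[mask] = np.nan
            np.fill_diagonal(vals, 0.0)
            D = dmatrix(vals)
            eps = float(rng.uniform(0.5, 2.0))
            min_pts = int(rng.integers(1, 6))
            out = cluster_modules(D, ClusteringParams(eps=eps, min_pts=min_pts))
            labels, types = density_cluster_bruteforce(vals, D.key_gene_ids, eps, min_pts)
            assert out.labels.tolist() == labels
            assert out.point_types == types

    def test_invariant_to_input_ordering(self, rng):
        vals = rng.uniform(0.5, 3.0, size=(15, 15))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        ids = [f"g{i:02d}" for i in range(15)]
        D = DistanceMatrix(ids, vals, np.isnan(vals))
        params = ClusteringParams(eps=1.4, min_pts=2)
        base = cluster_modules(D, params)
        by_gene = dict(zip(base.key_gene_ids, zip(base.labels, base.point_types)))

        perm = rng.permutation(15)
        vals_p = vals[np.ix_(perm, perm)]
        ids_p = [ids[i] for i in perm]
        shuffled = cluster_modules(
            DistanceMatrix(ids_p, vals_p, np.isnan(vals_p)), params)
        for gene, label, ptype in zip(shuffled.key_gene_ids, shuffled.labels,
                                      shuffled.point_types):
            assert by_gene[gene] == (label, ptype)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ClusteringParams(eps=0.0, min_pts=2)
        with pytest.raises(ValueError):
            ClusteringParams(eps=1.0, min_pts=0)
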