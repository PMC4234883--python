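import numpy as np
import networkx as nx
import pytest

from voxtome import (
    DistanceMatrix,
    ExpressionMatrix,
    LensValues,
    MapperParams,
    build_cover,
    build_nerve,
    cluster_bin,
    metric_svd_lens,
    pairwise_norm_correlation,
    run_mapper,
    segment_nerve,
    standardize_profiles,
)


def expr_from(values, genes=None, voxels=None):
    values = np.asarray(values, float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    voxels = voxels or [f"v{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(genes, voxels, values)


def dist(d, ids=None):
    d = np.asarray(d, float)
    ids = ids or [f"v{i}" for i in range(d.shape[0])]
    return DistanceMatrix(ids, d)


class TestStandardize:
    def test_per_voxel_zscore_population_convention(self):
        expr = expr_from([[1.0], [2.0], [3.0]])
        z = standardize_profiles(expr, axis="voxel")
        np.testing.assert_allclose(z[:, 0], [-1.224745, 0.0, 1.224745], atol=1e-6)

    def test_idempotent_on_standardized_vector(self):
        v = np.array([[-1.224745], [0.0], [1.224745]])
        z = standardize_profiles(v, axis="voxel")
        np.testing.assert_allclose(z, v, atol=1e-6)

    def test_constant_voxel_named_in_error(self):
        expr = expr_from([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]], voxels=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            standardize_profiles(expr, axis="voxel")

    def test_constant_gene_named_in_error(self):
        expr = expr_from([[1.0, 2.0], [3.0, 3.0]], genes=["ok", "flat"])
        with pytest.raises(ValueError, match="flat"):
            standardize_profiles(expr, axis="gene")

    def test_gene_axis_zscores_rows(self):
        expr = expr_from([[1.0, 2.0, 3.0], [10.0, 30.0, 20.0]])
        z = standardize_profiles(expr, axis="gene")
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1), 1.0, atol=1e-12)


class TestNormCorrelation:
    def test_identical_profiles_distance_zero(self):
        z = standardize_profiles(expr_from([[1.0, 1.0], [2.0, 2.0], [4.0, 4.0]]), axis="voxel")
        D = pairwise_norm_correlation(z, ["a", "b"])
        assert D.d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_negated_profile_distance_two(self):
        z = standardize_profiles(expr_from([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]]), axis="voxel")
        D = pairwise_norm_correlation(z, ["a", "b"])
        assert D.d[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_hand_computed_pearson(self):
        # r((1,2,3),(1,3,2)) = 0.5 so d = 0.5
        z = standardize_profiles(expr_from([[1.0, 1.0], [2.0, 3.0], [3.0, 2.0]]), axis="voxel")
        D = pairwise_norm_correlation(z, ["a", "b"])
        assert D.d[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_metric_properties_random(self):
        rng = np.random.default_rng(0)
        z = standardize_profiles(expr_from(rng.random(size=(30, 12))), axis="voxel")
        D = pairwise_norm_correlation(z, [f"v{i}" for i in range(12)])
        np.testing.assert_allclose(D.d, D.d.T, atol=1e-12)
        assert np.all(np.diag(D.d) == 0)
        assert D.d.min() >= 0 and D.d.max() <= 2

    def test_invariant_to_per_voxel_affine_rescaling(self):
        rng = np.random.default_rng(1)
        raw = rng.random(size=(25, 6)) * 100
        scaled = raw * rng.uniform(0.5, 5.0, size=6) + rng.uniform(0, 10, size=6)
        d1 = pairwise_norm_correlation(
            standardize_profiles(expr_from(raw), axis="voxel"), list("abcdef")
        )
        d2 = pairwise_norm_correlation(
            standardize_profiles(expr_from(scaled), axis="voxel"), list("abcdef")
        )
        np.testing.assert_allclose(d1.d, d2.d, atol=1e-10)


class TestMetricSvdLens:
    def test_collinear_three_points(self):
        D = dist([[0, 1, 2], [1, 0, 1], [2, 1, 0]])
        lens = metric_svd_lens(D, k=1)
        np.testing.assert_allclose(np.sort(lens.coords[:, 0]), [-1.0, 0.0, 1.0], atol=1e-9)
        # middle point stays in the middle
        assert abs(lens.coords[1, 0]) < 1e-9

    def test_collinear_second_axis_degenerate(self):
        D = dist([[0, 1, 2], [1, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError, match="smaller k"):
            metric_svd_lens(D, k=2)

    def test_equilateral_points_equidistant_from_centroid(self):
        # 3 mutually equidistant points embed exactly in the 2-D lens
        d = np.full((3, 3), 1.0)
        np.fill_diagonal(d, 0.0)
        lens = metric_svd_lens(dist(d), k=2)
        norms = np.linalg.norm(lens.coords, axis=1)
        np.testing.assert_allclose(norms, norms[0], atol=1e-9)

    def test_euclidean_configuration_recovered_up_to_isometry(self):
        from scipy.spatial import procrustes
        from scipy.spatial.distance import cdist

        rng = np.random.default_rng(2)
        pts = rng.random((20, 2)) * 0.5
        D = dist(cdist(pts, pts))
        lens = metric_svd_lens(D, k=2)
        _, _, disparity = procrustes(pts, lens.coords)
        assert disparity < 1e-8

    def test_sign_fix_makes_lens_deterministic(self):
        rng = np.random.default_rng(3)
        from scipy.spatial.distance import cdist

        pts = rng.random((15, 2))
        D = dist(cdist(pts, pts) / cdist(pts, pts).max() * 1.5)
        a = metric_svd_lens(D, k=2)
        b = metric_svd_lens(D, k=2)
        np.testing.assert_array_equal(a.coords, b.coords)
        for j in range(2):
            i = np.argmax(np.abs(a.coords[:, j]))
            assert a.coords[i, j] > 0


def lens1d(values):
    values = np.asarray(values, float)
    return LensValues([f"v{i}" for i in range(values.size)], values[:, None])


class TestBuildCover:
    def test_gain_one_is_partition(self):
        cover = build_cover(lens1d(np.arange(1, 9)), resolution=(4,), gain=(1.0,))
        bins = cover.bin_members()
        assert sorted(tuple(v) for v in bins.values()) == [
            (0, 1), (2, 3), (4, 5), (6, 7),
        ]

    def test_gain_two_middle_points_shared(self):
        cover = build_cover(lens1d([1.0, 2.0, 3.0, 4.0]), resolution=(2,), gain=(2.0,))
        bins = cover.bin_members()
        assert set(bins[(0,)]) == {0, 1, 2}
        assert set(bins[(1,)]) == {1, 2, 3}

    def test_equalized_base_occupancies_differ_by_at_most_one(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=103)
        cover = build_cover(lens1d(values), resolution=(10,), gain=(1.0,))
        sizes = sorted(len(v) for v in cover.bin_members().values())
        assert sizes[-1] - sizes[0] <= 1
        assert sum(sizes) == 103  # gain 1: every voxel in exactly one bin

    def test_membership_bounds_equal_width_intervals(self):
        # on evenly spaced values the quantile bins have equal width, so a
        # point lies in at most ceil(gain)+1 expanded intervals
        g = 2.5
        cover = build_cover(lens1d(np.linspace(0, 1, 80)), resolution=(8,), gain=(g,))
        counts = np.zeros(80, int)
        for members in cover.bin_members().values():
            counts[members] += 1
        assert counts.min() >= 1
        assert counts.max() <= int(np.ceil(g)) + 1

    def test_membership_covers_everything_random_inputs(self):
        # with unequal-frequency-induced widths the per-point bin count can
        # exceed the equal-width bound, but coverage and a generous cap hold
        rng = np.random.default_rng(5)
        for _ in range(10):
            values = rng.normal(size=80)
            g = 2.5
            cover = build_cover(lens1d(values), resolution=(8,), gain=(g,))
            counts = np.zeros(80, int)
            for members in cover.bin_members().values():
                counts[members] += 1
            assert counts.min() >= 1
            assert counts.max() <= 8  # never more than the resolution

    def test_resolution_exceeding_distinct_values_errors(self):
        with pytest.raises(ValueError, match="distinct"):
            build_cover(lens1d([1.0, 1.0, 2.0]), resolution=(3,), gain=(1.0,))

    def test_2d_cover_every_voxel_covered(self):
        rng = np.random.default_rng(6)
        lens = LensValues([f"v{i}" for i in range(60)], rng.normal(size=(60, 2)))
        cover = build_cover(lens, resolution=(6, 5), gain=(2.5, 4.0))
        covered = np.zeros(60, bool)
        for members in cover.bin_members().values():
            covered[members] = True
        assert covered.all()


class TestClusterBin:
    def test_singleton(self):
        D = dist(np.zeros((1, 1)))
        assert cluster_bin([0], D) == [[0]]

    def test_two_tight_pairs_split(self):
        d = np.array(
            [
                [0.00, 0.01, 1.00, 1.00],
                [0.01, 0.00, 1.00, 1.00],
                [1.00, 1.00, 0.00, 0.01],
                [1.00, 1.00, 0.01, 0.00],
            ]
        )
        parts = cluster_bin([0, 1, 2, 3], dist(d))
        assert sorted(sorted(p) for p in parts) == [[0, 1], [2, 3]]

    def test_all_equal_distances_single_cluster(self):
        d = np.full((5, 5), 0.7)
        np.fill_diagonal(d, 0.0)
        parts = cluster_bin(list(range(5)), dist(d))
        assert sorted(parts[0]) == [0, 1, 2, 3, 4]
        assert len(parts) == 1

    def test_identical_members_single_cluster(self):
        d = np.zeros((3, 3))
        parts = cluster_bin([0, 1, 2], dist(d))
        assert len(parts) == 1


class TestBuildNerve:
    def test_shared_voxel_edge_weight(self):
        g = build_nerve({(0,): [[0, 1]], (1,): [[1, 2]]}, ["a", "b", "c"])
        assert g.n_nodes == 2
        assert g.graph[0][1]["weight"] == 1

    def test_disjoint_clusters_no_edge(self):
        g = build_nerve({(0,): [[0, 1]], (1,): [[2, 3]]}, list("abcd"))
        assert g.graph.number_of_edges() == 0

    def test_random_instances_match_bruteforce_intersection(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(5, 50))
            bins = {}
            for b in range(int(rng.integers(2, 8))):
                members = rng.choice(n, size=rng.integers(1, n + 1), replace=False)
                split = rng.integers(1, len(members) + 1)
                clusters = [list(members[:split])]
                if split < len(members):
                    clusters.append(list(members[split:]))
                bins[(b,)] = clusters
            g = build_nerve(bins, [f"v{i}" for i in range(n)])
            nodes = list(g.graph.nodes)
            for i, a in enumerate(nodes):
                for b in nodes[i + 1 :]:
                    shared = g.node_members(a) & g.node_members(b)
                    assert g.graph.has_edge(a, b) == (len(shared) > 0)
                    if shared:
                        assert g.graph[a][b]["weight"] == len(shared)


class TestSegmentNerve:
    def test_two_components_auto(self):
        g = build_nerve(
            {(0,): [[0, 1]], (1,): [[1, 2]], (2,): [[3, 4]]}, list("abcde")
        )
        labels = segment_nerve(g)
        assert labels.k == 2
        assert labels.labels["a"] == labels.labels["b"] == labels.labels["c"]
        assert labels.labels["d"] == labels.labels["e"]
        assert labels.labels["a"] != labels.labels["d"]

    def test_chain_with_heavy_edge_k2(self):
        # A{0..3}, B{1..4} share 3 voxels; C{4,5} shares 1 with B
        g = build_nerve(
            {(0,): [[0, 1, 2, 3]], (1,): [[1, 2, 3, 4]], (2,): [[4, 5]]},
            [f"v{i}" for i in range(6)],
        )
        labels = segment_nerve(g, k=2)
        assert labels.k == 2
        same = {labels.labels[f"v{i}"] for i in (0, 1, 2, 3)}
        assert len(same) == 1
        assert labels.labels["v5"] != labels.labels["v0"]

    def test_k_equals_nodes(self):
        g = build_nerve(
            {(0,): [[0]], (1,): [[1]], (2,): [[2]]}, list("abc")
        )
        labels = segment_nerve(g, k=3)
        assert labels.k == 3

    def test_k_above_node_count_errors(self):
        g = build_nerve({(0,): [[0]]}, ["a"])
        with pytest.raises(ValueError, match="exceeds"):
            segment_nerve(g, k=2)


class TestRunMapper:
    def test_duplicate_profiles_share_nodes_and_label(self):
        rng = np.random.default_rng(8)
        values = rng.random((40, 8)) * 100
        values[:, 3] = values[:, 5]  # two identical voxels
        expr = expr_from(values)
        graph, labels = run_mapper(expr, MapperParams(resolution=(3, 2), gain=(2.0, 2.0)))
        for n in graph.graph.nodes:
            members = graph.node_members(n)
            assert (3 in members) == (5 in members)
        assert labels.labels["v3"] == labels.labels["v5"]

    def test_deterministic_given_seed(self, small_expression):
        expr, grid, truth = small_expression
        g1, l1 = run_mapper(expr, MapperParams(seed=11))
        g2, l2 = run_mapper(expr, MapperParams(seed=11))
        assert l1.labels == l2.labels
        assert {n: g1.node_members(n) for n in g1.graph.nodes} == {
            n: g2.node_members(n) for n in g2.graph.nodes
        }
        assert set(g1.graph.edges) == set(g2.graph.edges)

    def test_small_nerve_matches_hand_enumeration(self):
        # 5 voxels, 2 well-separated pairs + 1 outlier; resolution (2,2)
        # keeps the construction small enough to enumerate by hand via the
        # cover itself.
        rng = np.random.default_rng(9)
        base = rng.random((30, 5))
        base[:, 1] = base[:, 0] + 0.01 * rng.random(30)
        base[:, 3] = base[:, 2] + 0.01 * rng.random(30)
        expr = expr_from(base * 1000)
        params = MapperParams(resolution=(2, 2), gain=(1.0, 1.0))
        graph, _ = run_mapper(expr, params)
        # with gain 1 the cover is a partition: nodes are disjoint,
        # so the nerve has no edges and every voxel sits in exactly one node
        assert graph.graph.number_of_edges() == 0
        counts = np.zeros(5, int)
        for n in graph.graph.nodes:
            for v in graph.node_members(n):
                counts[v] += 1
        assert counts.tolist() == [1, 1, 1, 1, 1]

    def test_every_voxel_labeled(self, small_expression):
        expr, grid, truth = small_expression
        _, labels = run_mapper(expr)
        assert set(labels.labels) == set(expr.voxel_ids)
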