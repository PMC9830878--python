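"""MST construction, subgraph splitting, centers, densities and the overlap."""

import itertools

import networkx as nx
import numpy as np
import pytest

from xylolink.io import LabeledEmbedding
from xylolink.overlap import (
    MSTOverlap,
    OverlapConfig,
    build_mst,
    component_centers,
    density_grid,
    overlap_statistic,
    split_subgraphs,
    weighted_density_map,
)
from xylolink.simulate import simulate_embedding_pair


def _kruskal_weight(points):
    """Brute-force Kruskal oracle: total MST weight."""
    n = len(points)
    edges = sorted(
        (np.linalg.norm(points[i] - points[j]), i, j)
        for i, j in itertools.combinations(range(n), 2)
    )
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    total, used = 0.0, 0
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            total += w
            used += 1
            if used == n - 1:
                break
    return total


class TestBuildMst:
    def test_collinear_forced_geometry(self):
        edges = build_mst(np.array([[0.0, 0], [1, 0], [3, 0]]))
        assert {(int(i), int(j)) for i, j, _ in edges} == {(0, 1), (1, 2)}
        assert edges[:, 2].sum() == pytest.approx(3.0)

    def test_two_points_single_edge(self):
        edges = build_mst(np.array([[0.0, 0], [0, 2]]))
        assert edges.shape == (1, 3) and edges[0, 2] == pytest.approx(2.0)

    def test_weight_matches_kruskal_and_prim_oracles(self, rng):
        pts = rng.uniform(size=(100, 2))
        edges = build_mst(pts)
        assert len(edges) == 99
        assert edges[:, 2].sum() == pytest.approx(_kruskal_weight(pts), abs=1e-9)
        g = nx.Graph()
        for i, j in itertools.combinations(range(100), 2):
            g.add_edge(i, j, weight=float(np.linalg.norm(pts[i] - pts[j])))
        prim = nx.minimum_spanning_tree(g, algorithm="prim")
        assert edges[:, 2].sum() == pytest.approx(prim.size(weight="weight"), abs=1e-9)

    def test_connected_and_acyclic(self, rng):
        pts = rng.normal(size=(60, 2))
        edges = build_mst(pts)
        g = nx.Graph((int(i), int(j)) for i, j, _ in edges)
        assert nx.is_tree(g) and g.number_of_nodes() == 60

    def test_duplicate_points_legal(self):
        edges = build_mst(np.array([[0.0, 0], [0, 0], [1, 0]]))
        assert len(edges) == 2 and edges[:, 2].min() == 0.0

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            build_mst(np.array([[0.0, 0]]))


class TestSplitSubgraphs:
    def test_all_same_label_single_component(self):
        pts = np.random.default_rng(0).normal(size=(10, 2))
        edges = build_mst(pts)
        with pytest.raises(ValueError):
            split_subgraphs(edges, np.repeat("A", 10))

    def test_alternating_path_all_singletons(self):
        pts = np.array([[0.0, 0], [1, 0], [2, 0], [3, 0]])
        edges = build_mst(pts)
        comp, k = split_subgraphs(edges, np.asarray(list("ABAB")))
        assert k == 3 and len(set(comp)) == 4

    def test_component_count_identity(self, rng):
        """#components == #deleted cross-label edges + 1, for random labelings."""
        pts = rng.normal(size=(80, 2))
        edges = build_mst(pts)
        for trial in range(20):
            labels = rng.choice(["A", "B"], size=80)
            if len(set(labels)) < 2:
                continue
            comp, k = split_subgraphs(edges, labels)
            assert comp.max() + 1 == k + 1
            # every component single-label
            for c in range(comp.max() + 1):
                assert len(set(labels[comp == c])) == 1


class TestCenters:
    def test_singleton_is_its_own_center(self):
        pts = np.array([[0.0, 0], [10, 0], [10.5, 0]])
        edges = build_mst(pts)
        comp, _ = split_subgraphs(edges, np.asarray(["A", "B", "B"]))
        centers = component_centers(comp, edges, pts)
        assert pts[centers[comp[0]]].tolist() == [0.0, 0.0]

    def test_three_node_path_middle(self):
        pts = np.array([[0.0, 0], [1, 0], [2, 0]])
        edges = build_mst(pts)
        comp = np.zeros(3, dtype=int)
        centers = component_centers(comp, edges, pts)
        assert centers[0] == 1

    def test_matches_all_pairs_brute_force(self, rng):
        """Center equals the argmin of summed tree-path distances computed by
        networkx all-pairs Dijkstra on components up to 50 nodes."""
        pts = rng.normal(size=(50, 2))
        edges = build_mst(pts)
        labels = rng.choice(["A", "B"], size=50)
        comp, _ = split_subgraphs(edges, labels)
        centers = component_centers(comp, edges, pts)
        g = nx.Graph()
        g.add_nodes_from(range(50))
        for i, j, w in edges:
            if comp[int(i)] == comp[int(j)]:
                g.add_edge(int(i), int(j), weight=float(w))
        for c in range(comp.max() + 1):
            nodes = np.where(comp == c)[0]
            sums = {}
            for u in nodes:
                dist = nx.single_source_dijkstra_path_length(g, int(u))
                sums[int(u)] = sum(dist[int(v)] for v in nodes)
            best = min(sums.values())
            winners = {u for u, s in sums.items() if s <= best + 1e-9 * max(best, 1e-12)}
            assert centers[c] in winners
            assert centers[c] == min(winners)  # lowest-index tie-break


class TestDensity:
    def test_single_center_unit_mass_on_grid(self, rng):
        cells = {"A": rng.normal(size=(50, 2)), "B": rng.normal(size=(50, 2)) + 8}
        centers = {"A": cells["A"][:1], "B": cells["B"][:1]}
        fields = weighted_density_map(centers, cells)
        xs, ys, _ = density_grid(fields, np.vstack(list(cells.values())))
        area = (xs[1] - xs[0]) * (ys[1] - ys[0])
        quer = np.column_stack([g.ravel() for g in np.meshgrid(xs, ys, indexing="ij")])
        mass = fields["A"].density(quer).sum() * area
        assert mass == pytest.approx(1.0, abs=1e-3)

    def test_mirror_symmetry(self):
        cells = {"A": np.array([[-1.0, 0], [-2, 1], [-3, -1]]),
                 "B": np.array([[1.0, 0], [2, 1], [3, -1]])}
        centers = {"A": np.array([[-2.0, 0]]), "B": np.array([[2.0, 0]])}
        fields = weighted_density_map(centers, cells)
        pts = np.array([[0.5, 0.3], [-0.5, 0.3]])
        d = fields["A"].weighted(pts) + fields["B"].weighted(pts)
        assert d[0] == pytest.approx(d[1], rel=1e-9)

    def test_weight_scales_linearly_with_center_count(self):
        from xylolink.overlap import SpeciesDensityField

        cells = {"A": np.random.default_rng(0).normal(size=(40, 2)),
                 "B": np.random.default_rng(1).normal(size=(40, 2))}
        c1 = {"A": np.array([[0.0, 0]]), "B": np.array([[1.0, 1]])}
        f1 = weighted_density_map(c1, cells)
        # doubling m_S with the same KDE shape doubles w_S everywhere
        doubled = SpeciesDensityField(f1["A"].centers, f1["A"].bandwidth,
                                      2 * f1["A"].weight)
        pts = np.random.default_rng(2).normal(size=(20, 2))
        assert np.allclose(doubled.weighted(pts), 2 * f1["A"].weighted(pts))
        # and weighted_density_map's weight is m_S * n_S / n by construction
        c2 = {"A": np.array([[0.0, 0], [0.0, 0]]), "B": c1["B"]}
        f2 = weighted_density_map(c2, cells)
        assert f2["A"].weight == pytest.approx(2 * f1["A"].weight)

    def test_empty_center_set_rejected(self):
        with pytest.raises(ValueError):
            weighted_density_map({"A": np.empty((0, 2))}, {"A": np.zeros((3, 2))})


class TestOverlapStatistic:
    def test_identical_distributions_high_overlap(self):
        emb = simulate_embedding_pair(2000, 0.0, seed=11, n_components=3)
        res = overlap_statistic(emb)
        assert res.overlap_pct >= 95.0
        assert res.bin_proportions.sum() == pytest.approx(1.0)
        assert res.n_subgraphs == res.n_removed + 1

    def test_separated_blobs_low_overlap_reference_mode(self):
        ref = overlap_statistic(simulate_embedding_pair(1000, 0.0, seed=12))
        emb = simulate_embedding_pair(1000, 20.0, seed=12)
        cfg = OverlapConfig(mode="reference", ref_scale=ref.scale_constants)
        res = overlap_statistic(emb, cfg)
        assert res.overlap_pct <= 5.0

    def test_single_species_rejected(self):
        emb = LabeledEmbedding(
            ["a", "b", "c"], np.random.default_rng(0).normal(size=(3, 2)),
            ["A", "A", "A"], ["k"] * 3)
        with pytest.raises(ValueError):
            overlap_statistic(emb)

    def test_rigid_motion_and_scale_invariance(self):
        emb = simulate_embedding_pair(300, 2.0, seed=5)
        base = overlap_statistic(emb).overlap_pct
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = LabeledEmbedding(
            emb.cell_ids, 3.0 * emb.coordinates + np.array([5.0, -2.0]),
            emb.species, emb.cluster)
        assert overlap_statistic(moved).overlap_pct == pytest.approx(base, abs=1e-9)
        rotated = LabeledEmbedding(
            emb.cell_ids, emb.coordinates @ rot.T, emb.species, emb.cluster)
        # per-axis (kde2d-style) bandwidths make rotation invariance only
        # approximate; translation/scaling above are exact
        assert overlap_statistic(rotated).overlap_pct == pytest.approx(base, abs=4.0)

    def test_cross_edge_count_near_friedman_rafsky_expectation(self):
        """Identical distributions: E[k] ~ 2 n_A n_B / n (within 20%)."""
        n = 1000
        ks = []
        for seed in range(10):
            emb = simulate_embedding_pair(n, 0.0, seed=30 + seed)
            res = overlap_statistic(emb)
            ks.append(res.n_removed)
        expect = 2 * n * n / (2 * n)
        assert abs(np.mean(ks) - expect) / expect < 0.2

    def test_separation_monotonicity(self):
        """Median O (reference mode, anchored at coincident blobs) is
        non-increasing over 6 separation steps, 10 seeds each."""
        seps = [0.0, 2.0, 4.0, 6.0, 8.0, 10.0]
        medians = []
        for sep in seps:
            vals = []
            for seed in range(10):
                ref = overlap_statistic(simulate_embedding_pair(300, 0.0, seed=50 + seed))
                emb = simulate_embedding_pair(300, sep, seed=50 + seed)
                cfg = OverlapConfig(mode="reference", ref_scale=ref.scale_constants)
                vals.append(overlap_statistic(emb, cfg).overlap_pct)
            medians.append(np.median(vals))
        assert all(medians[i + 1] <= medians[i] + 1e-9 for i in range(len(seps) - 1))

    def test_estimator_interface(self):
        emb = simulate_embedding_pair(200, 1.0, seed=3)
        est = MSTOverlap().fit(emb.coordinates, emb.species)
        assert 0.0 <= est.overlap_ <= 1.0
        assert est.n_subgraphs_ == est.n_cross_edges_ + 1
        assert est.get_params()["n_bins"] == 500
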