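import itertools

import networkx as nx
import numpy as np
import pytest

from ylineage.diversity import count_segregating_sites, hamming
from ylineage.phylo import (
    DistanceMatrix,
    hamming_matrix,
    minimum_spanning_network,
    mjn,
    mp_prune,
    export_network,
    upgma,
)
from ylineage.simulate import SimConfig, simulate


class TestHammingMatrix:
    def test_trivial(self):
        dm = hamming_matrix({"a": ("G", "T"), "b": ("G", "T")})
        assert dm.d[0, 1] == 0

    def test_single_difference(self):
        dm = hamming_matrix({"a": ("G", "T"), "b": ("G", "A")})
        assert dm.d[0, 1] == 1

    def test_matches_site_loop_oracle(self, rng):
        labels = [f"h{i}" for i in range(6)]
        vecs = {l: tuple(rng.choice(["A", "C", "G", "T"], 10)) for l in labels}
        dm = hamming_matrix(vecs)
        for i, j in itertools.combinations(range(6), 2):
            brute = sum(
                a != b for a, b in zip(vecs[labels[i]], vecs[labels[j]])
            )
            assert dm.d[i, j] == brute

    def test_rejects_asymmetry(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestUpgma:
    def test_three_taxon_ultrametric(self):
        dm = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float),
        )
        assert upgma(dm).to_newick() == "((A:1,B:1):1,C:2);"

    def test_two_taxa(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 3], [3, 0]], dtype=float))
        assert upgma(dm).to_newick() == "(A:1.5,B:1.5);"

    def test_single_taxon_rejected(self):
        with pytest.raises(ValueError):
            upgma(DistanceMatrix(["A"], np.zeros((1, 1))))

    @staticmethod
    def _random_clock_tree(n_leaves, rng):
        """Simulate a clock tree by successive merges at increasing heights."""
        clusters = {f"T{i:02d}": (f"T{i:02d}", 0.0) for i in range(n_leaves)}
        height = 0.0
        mrca = {}
        while len(clusters) > 1:
            height += float(rng.uniform(0.5, 1.5))
            a, b = sorted(rng.choice(sorted(clusters), 2, replace=False))
            for x in _leaves(clusters[a][0]):
                for y in _leaves(clusters[b][0]):
                    mrca[frozenset((x, y))] = height
            clusters[f"({clusters[a][0]},{clusters[b][0]})"] = (
                f"({clusters[a][0]},{clusters[b][0]})",
                height,
            )
            del clusters[a], clusters[b]
        return mrca

    def test_recovers_simulated_clock_tree(self, rng):
        """UPGMA reconstructs the exact clades of an ultrametric clock tree."""
        for _ in range(5):
            n = int(rng.integers(4, 9))
            mrca = self._random_clock_tree(n, rng)
            leaves = sorted({x for key in mrca for x in key})
            idx = {l: i for i, l in enumerate(leaves)}
            d = np.zeros((len(leaves), len(leaves)))
            for key, h in mrca.items():
                x, y = sorted(key)
                d[idx[x], idx[y]] = d[idx[y], idx[x]] = 2 * h
            tree = upgma(DistanceMatrix(leaves, d))
            observed = _clades(tree)
            expected = _true_clades(leaves, mrca)
            assert observed == expected

    def test_agrees_with_independent_average_linkage(self, rng):
        """Cophenetic distances match scipy's average-linkage clustering on
        generic (tie-free) random matrices."""
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        for _ in range(3):
            n = 7
            condensed = rng.uniform(1.0, 10.0, n * (n - 1) // 2)
            mat = squareform(condensed)
            labels = [f"L{i}" for i in range(n)]
            tree = upgma(DistanceMatrix(labels, mat))
            # my cophenetic distance: twice the MRCA height
            coph_mine = {}

            def walk(node):
                for a in node.children:
                    for b in node.children:
                        if a is b:
                            continue
                        for x in a.leaf_labels():
                            for y in b.leaf_labels():
                                coph_mine[frozenset((x, y))] = 2 * node.height
                for c in node.children:
                    walk(c)

            walk(tree)
            coph_scipy = squareform(cophenet(linkage(condensed, method="average")))
            for i, j in itertools.combinations(range(n), 2):
                assert coph_mine[frozenset((labels[i], labels[j]))] == pytest.approx(
                    coph_scipy[i, j]
                )

    def test_ultrametric_output(self, default_sim):
        from ylineage.markers import collapse_haplotypes

        haps = collapse_haplotypes(default_sim.records, default_sim.panel)
        dm = hamming_matrix({h.name: h.call_vector for h in haps})
        tree = upgma(dm)
        depths = _leaf_depths(tree)
        assert max(depths.values()) - min(depths.values()) < 1e-9

    def test_deterministic_newick(self, default_sim):
        from ylineage.markers import collapse_haplotypes

        haps = collapse_haplotypes(default_sim.records, default_sim.panel)
        dm = hamming_matrix({h.name: h.call_vector for h in haps})
        assert upgma(dm).to_newick() == upgma(dm).to_newick()


def _leaf_depths(tree):
    """Root-to-leaf path lengths along branch lengths."""
    depths = {}

    def walk(node, dist):
        if node.is_leaf:
            depths[node.label] = dist
        for c in node.children:
            walk(c, dist + node.height - c.height)

    walk(tree, 0.0)
    return depths


def _leaves(newick_label):
    return [s for s in newick_label.replace("(", " ").replace(")", " ")
            .replace(",", " ").split() if s]


def _clades(tree):
    out = set()

    def walk(node):
        labs = frozenset(node.leaf_labels())
        if len(labs) > 1:
            out.add(labs)
        for c in node.children:
            walk(c)

    walk(tree)
    return out


def _true_clades(leaves, mrca):
    """Clades implied by the MRCA heights of the simulated clock tree."""
    heights = sorted({h for h in mrca.values()})
    clades = set()
    for h in heights:
        # union-find: leaves joined at height <= h form nested clades
        parent = {l: l for l in leaves}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for key, hh in mrca.items():
            if hh <= h:
                x, y = sorted(key)
                parent[find(x)] = find(y)
        groups = {}
        for l in leaves:
            groups.setdefault(find(l), set()).add(l)
        for g in groups.values():
            if len(g) > 1:
                clades.add(frozenset(g))
    return clades


class TestMjn:
    def test_path_without_medians(self):
        net = mjn({"a": ("0", "0"), "b": ("0", "1"), "c": ("1", "1")})
        assert net.medians == []
        assert sorted(map(tuple, map(sorted, net.graph.edges))) == [
            ("a", "b"), ("b", "c")
        ]

    def test_steiner_median_for_symmetric_triplet(self):
        net = mjn(
            {"a": ("0", "1", "1"), "b": ("1", "0", "1"), "c": ("1", "1", "0")}
        )
        assert len(net.medians) == 1
        (mv,) = net.medians
        assert net.vectors[mv] == ("1", "1", "1")
        assert sorted(net.graph.neighbors(mv)) == ["a", "b", "c"]
        assert all(net.graph.get_edge_data(mv, x)["length"] == 1 for x in "abc")

    def test_median_matches_exhaustive_steiner_point_search(self):
        """The added median is the unique optimal Steiner point over {0,1}^3."""
        vs = {"a": ("0", "1", "1"), "b": ("1", "0", "1"), "c": ("1", "1", "0")}
        best = min(
            itertools.product("01", repeat=3),
            key=lambda m: sum(hamming(m, v) for v in vs.values()),
        )
        cost = sum(hamming(best, v) for v in vs.values())
        assert best == ("1", "1", "1") and cost == 3
        net = mjn(vs)
        assert net.total_length == cost

    def test_star_genealogy_recovers_star(self):
        L = 8
        root = tuple("G") * L
        haps = {"root": root}
        for k in range(5):
            v = list(root)
            v[k] = "A"
            haps[f"d{k}"] = tuple(v)
        net = mjn(haps)
        assert net.medians == []
        assert net.graph.degree("root") == 5
        assert net.graph.number_of_edges() == 5

    def test_msn_connections_realized_at_exact_cost(self, default_sim):
        """Each link of the observed-haplotype spanning network survives in
        the final network as a geodesic of exactly its length."""
        from ylineage.markers import collapse_haplotypes

        haps = collapse_haplotypes(default_sim.records, default_sim.panel)
        vectors = {h.name: h.call_vector for h in haps}
        msn = minimum_spanning_network(vectors)
        net = mjn(vectors)
        for u, v in msn.edges:
            sp = nx.shortest_path_length(net.graph, u, v, weight="length")
            assert sp == hamming(vectors[u], vectors[v])

    def test_duplicate_vectors_rejected(self):
        with pytest.raises(ValueError):
            mjn({"a": ("0",), "b": ("0",)})


def _all_min_spanning_edge_union(graph, observed):
    """Brute-force Steiner oracle: try every median subset, enumerate every
    spanning tree by edge combinations, and return (min length, edge union)."""
    medians = sorted(set(graph.nodes) - set(observed))
    best_w = None
    union = set()
    for r in range(len(medians) + 1):
        for subset in itertools.combinations(medians, r):
            nodes = sorted(set(observed) | set(subset))
            sub = graph.subgraph(nodes)
            edges = list(sub.edges(data=True))
            if len(edges) < len(nodes) - 1:
                continue
            for combo in itertools.combinations(edges, len(nodes) - 1):
                t = nx.Graph()
                t.add_nodes_from(nodes)
                t.add_edges_from((u, v) for u, v, _ in combo)
                if not nx.is_connected(t):
                    continue
                w = sum(d["length"] for _, _, d in combo)
                key_edges = {tuple(sorted((u, v))) for u, v, _ in combo}
                if best_w is None or w < best_w - 1e-9:
                    best_w, union = w, set(key_edges)
                elif abs(w - best_w) <= 1e-9:
                    union |= key_edges
    return best_w, union


class TestMpPrune:
    def test_minimal_path_unchanged(self):
        net = mjn({"a": ("0", "0"), "b": ("0", "1"), "c": ("1", "1")})
        pruned = mp_prune(net)
        assert sorted(map(tuple, map(sorted, pruned.graph.edges))) == sorted(
            map(tuple, map(sorted, net.graph.edges))
        )

    def test_matches_exhaustive_steiner_oracle_on_random_instances(self):
        """Pruned network = union of all minimum-length spanning trees of the
        observed haplotypes through the admissible median vectors."""
        rng = np.random.default_rng(99)
        for trial in range(8):
            k = int(rng.integers(4, 8))
            L = int(rng.integers(5, 8))
            vecs = {}
            while len(vecs) < k:
                v = tuple(str(b) for b in rng.integers(0, 2, L))
                vecs[f"h{len(vecs)}"] = v
            if len(set(vecs.values())) < k:
                continue
            net = mjn(vecs)
            pruned = mp_prune(net)
            best_w, union = _all_min_spanning_edge_union(net.graph, net.observed)
            got = {tuple(sorted(e)) for e in pruned.graph.edges}
            assert got == union
            assert pruned.total_length >= best_w  # union is a supergraph of each tree

    def test_median_degree_after_pruning(self, default_sim):
        from ylineage.markers import collapse_haplotypes

        haps = collapse_haplotypes(default_sim.records, default_sim.panel)
        net = mp_prune(mjn({h.name: h.call_vector for h in haps}))
        assert all(net.graph.degree(m) >= 3 for m in net.medians)

    def test_perfect_phylogeny_tree_length_equals_segregating_sites(self):
        """Infinite-sites haplotypes prune to a tree whose total length is the
        segregating-site count."""
        sim = simulate(
            SimConfig(seed=11, n_samples=120, cn_change_rate=0.0,
                      split_change_rate=0.0, dropout_rate=0.0)
        )
        from ylineage.markers import collapse_haplotypes

        haps = collapse_haplotypes(sim.records, sim.panel)
        vectors = {h.name: h.call_vector for h in haps}
        S = count_segregating_sites(list(vectors.values()))
        net = mp_prune(mjn(vectors))
        assert nx.is_tree(net.graph)
        assert net.total_length == S


class TestExport:
    def test_two_node_network(self, tmp_path):
        net = mjn({"a": ("0",), "b": ("1",)})
        edges, gml = export_network(net, tmp_path / "net")
        lines = edges.read_text().strip().splitlines()
        assert lines[0] == "node1\tnode2\tlength\tsites"
        assert len(lines) == 2

    def test_gml_roundtrip_preserves_attributes(self, tmp_path):
        net = mjn(
            {"a": ("0", "1", "1"), "b": ("1", "0", "1"), "c": ("1", "1", "0")},
            counts={"a": 5, "b": 2, "c": 1},
        )
        _, gml = export_network(net, tmp_path / "net")
        back = nx.read_gml(str(gml))
        assert back.nodes["a"]["count"] == 5
        assert back.nodes["a"]["kind"] == "observed"
        assert set(back.nodes) == set(net.graph.nodes)

    def test_simulated_node_count(self, default_sim, tmp_path):
        from ylineage.markers import collapse_haplotypes

        haps = collapse_haplotypes(default_sim.records, default_sim.panel)
        net = mjn({h.name: h.call_vector for h in haps})
        edges, _ = export_network(net, tmp_path / "sim")
        assert net.graph.number_of_nodes() == len(haps) + len(net.medians)
        # determinism: identical input -> byte-identical export
        edges2, _ = export_network(net, tmp_path / "sim2")
        assert edges.read_text() == edges2.read_text()
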