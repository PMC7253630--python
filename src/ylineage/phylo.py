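"""Phylogenetic reconstruction: distances, UPGMA trees, median-joining networks.

Haplotype call vectors are compared site-by-site (Hamming distance; a double
call is one state).  UPGMA builds an ultrametric dendrogram by average-linkage
agglomeration with deterministic lexicographic tie-breaking.  The median-joining
network follows Bandelt, Forster & Roehl (1999): iterate between an
epsilon-relaxed minimum spanning network and the addition of quasi-median
(consensus) vectors for connected triplets, then drop obsolete medians.
MP ("maximum parsimony") pruning keeps exactly the links and median vectors
that lie on at least one minimum-length tree spanning the observed haplotypes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .diversity import hamming

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "HaploNetwork",
    "hamming_matrix",
    "upgma",
    "mjn",
    "mp_prune",
    "export_network",
    "minimum_spanning_network",
]


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric non-negative matrix with zero diagonal over ordered labels."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T) or np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.d):
                fh.write(lab + "\t" + "\t".join(f"{v:g}" for v in row) + "\n")
        return path


def hamming_matrix(
    haplotypes: Mapping[str, Sequence[str]] | Sequence[tuple[str, Sequence[str]]]
) -> DistanceMatrix:
    """Pairwise site-difference counts between labelled call vectors."""
    items = list(haplotypes.items()) if isinstance(haplotypes, Mapping) else list(haplotypes)
    labels = [lab for lab, _ in items]
    vecs = [tuple(v) for _, v in items]
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = hamming(vecs[i], vecs[j])
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Rooted ultrametric tree node; height is half the merge distance."""

    label: str | None = None
    height: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def representative(self) -> str:
        return self.label if self.is_leaf else min(c.representative for c in self.children)

    def leaf_labels(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return [lab for c in self.children for lab in c.leaf_labels()]

    def to_newick(self) -> str:
        return self._newick(parent_height=None) + ";"

    def _newick(self, parent_height: float | None) -> str:
        if self.is_leaf:
            core = self.label
        else:
            kids = sorted(self.children, key=lambda c: c.representative)
            core = "(" + ",".join(c._newick(self.height) for c in kids) + ")"
        if parent_height is None:
            return core
        return f"{core}:{parent_height - self.height:g}"


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage agglomeration into a rooted ultrametric tree.

    Node height is half the merge distance; distance ties merge the pair
    whose (sorted) representative labels are lexicographically smallest,
    so identical input yields byte-identical Newick output.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("UPGMA needs >= 2 taxa")
    clusters: dict[str, TreeNode] = {
        lab: TreeNode(label=lab) for lab in dm.labels
    }
    sizes = {lab: 1 for lab in dm.labels}
    idx = {lab: i for i, lab in enumerate(dm.labels)}
    dist: dict[frozenset[str], float] = {
        frozenset((a, b)): dm.d[idx[a], idx[b]]
        for a, b in itertools.combinations(dm.labels, 2)
    }
    while len(clusters) > 1:
        best = min(
            (
                (dist[frozenset((a, b))], tuple(sorted((a, b))))
                for a, b in itertools.combinations(sorted(clusters), 2)
            ),
            key=lambda t: (t[0], t[1]),
        )
        dmin, (a, b) = best
        node = TreeNode(height=dmin / 2.0, children=[clusters[a], clusters[b]])
        rep = node.representative
        na, nb = sizes[a], sizes[b]
        updates = {}
        for other in list(clusters):
            if other in (a, b):
                continue
            updates[frozenset((rep, other))] = (
                na * dist[frozenset((a, other))] + nb * dist[frozenset((b, other))]
            ) / (na + nb)
        for other in list(clusters):
            dist.pop(frozenset((a, other)), None)
            dist.pop(frozenset((b, other)), None)
        dist.update(updates)
        del clusters[a], clusters[b], sizes[a], sizes[b]
        clusters[rep] = node
        sizes[rep] = na + nb
    return next(iter(clusters.values()))


# ---------------------------------------------------------------------------
# median-joining networks
# ---------------------------------------------------------------------------

@dataclass
class HaploNetwork:
    """Observed haplotypes plus inferred median vectors with mutation-labelled links."""

    graph: nx.Graph
    vectors: dict[str, tuple[str, ...]]
    observed: frozenset[str]
    site_labels: tuple[str, ...] = ()

    @property
    def medians(self) -> list[str]:
        return sorted(set(self.vectors) - self.observed)

    @property
    def total_length(self) -> float:
        return sum(d["length"] for _, _, d in self.graph.edges(data=True))


def minimum_spanning_network(
    vectors: Mapping[str, tuple[str, ...]], epsilon: int = 0
) -> nx.Graph:
    """Epsilon-relaxed minimum spanning network over labelled vectors.

    Distance levels are scanned in ascending order; at each level every pair
    whose endpoints were in different components *before the level* is linked.
    With epsilon = 0 scanning stops at the level that first connects the
    graph; epsilon > 0 admits that many further levels.
    """
    labels = sorted(vectors)
    g = nx.Graph()
    g.add_nodes_from(labels)
    if len(labels) < 2:
        return g
    pair_d = {
        (u, v): hamming(vectors[u], vectors[v])
        for u, v in itertools.combinations(labels, 2)
    }
    levels = sorted(set(pair_d.values()))
    uf = nx.utils.UnionFind(labels)
    connected_level: int | None = None
    for delta in levels:
        if connected_level is not None and delta > connected_level + epsilon:
            break
        before = {lab: uf[lab] for lab in labels}
        for (u, v), d in pair_d.items():
            if d == delta and before[u] != before[v]:
                g.add_edge(u, v, length=d)
                uf.union(u, v)
        if connected_level is None and len(set(uf[lab] for lab in labels)) == 1:
            connected_level = delta
    return g


def _quasi_medians(
    u: tuple[str, ...], v: tuple[str, ...], w: tuple[str, ...],
    max_expansion: int = 729,
) -> list[tuple[str, ...]]:
    """Site-wise majority consensus; sites where all three states differ
    expand into every combination of the observed states."""
    per_site: list[tuple[str, ...]] = []
    n_comb = 1
    for a, b, c in zip(u, v, w):
        states = (a, b, c)
        majority = [s for s in set(states) if states.count(s) >= 2]
        if majority:
            per_site.append((majority[0],))
        else:
            per_site.append(tuple(sorted(set(states))))
            n_comb *= len(set(states))
        if n_comb > max_expansion:
            return []  # degenerate triplet: skip rather than explode
    return [tuple(comb) for comb in itertools.product(*per_site)]


def mjn(
    haplotypes: Mapping[str, tuple[str, ...]] | Sequence[tuple[str, tuple[str, ...]]],
    epsilon: int = 0,
    counts: Mapping[str, int] | None = None,
    groups: Mapping[str, Mapping[str, int]] | None = None,
    site_labels: Sequence[str] = (),
    max_iter: int = 50,
) -> HaploNetwork:
    """Median-joining network over observed haplotype call vectors.

    Repeats until fixation: build the epsilon-relaxed minimum spanning
    network; for every connected triplet (two links sharing a node) compute
    quasi-medians; add the novel medians whose connection cost
    d(m,u)+d(m,v)+d(m,w) is within epsilon of the round's minimum.  Obsolete
    median vectors (degree <= 2 in the final spanning network — they can
    never shorten it, Hamming distance being a metric) are removed.
    """
    items = (
        list(haplotypes.items())
        if isinstance(haplotypes, Mapping)
        else list(haplotypes)
    )
    vectors: dict[str, tuple[str, ...]] = {lab: tuple(v) for lab, v in items}
    if len(vectors) < 2:
        raise ValueError("a network needs >= 2 distinct haplotypes")
    if len(set(vectors.values())) != len(vectors):
        raise ValueError("haplotype vectors must be distinct")
    observed = frozenset(vectors)
    seen_vectors = set(vectors.values())
    n_median = 0

    for _ in range(max_iter):
        g = minimum_spanning_network(vectors, epsilon)
        candidates: dict[tuple[str, ...], int] = {}
        for v_node in sorted(g.nodes):
            nbrs = sorted(g.neighbors(v_node))
            for u_node, w_node in itertools.combinations(nbrs, 2):
                for m in _quasi_medians(
                    vectors[u_node], vectors[v_node], vectors[w_node]
                ):
                    if m in seen_vectors:
                        continue
                    cost = (
                        hamming(m, vectors[u_node])
                        + hamming(m, vectors[v_node])
                        + hamming(m, vectors[w_node])
                    )
                    prev = candidates.get(m)
                    if prev is None or cost < prev:
                        candidates[m] = cost
        if not candidates:
            break
        lam = min(candidates.values())
        added = False
        for m in sorted(c for c, cost in candidates.items() if cost <= lam + epsilon):
            n_median += 1
            vectors[f"mv{n_median}"] = m
            seen_vectors.add(m)
            added = True
        if not added:  # pragma: no cover - lam is the min, so something adds
            break

    # obsolete-median removal: rebuild and strip degree-<=2 medians to fixation
    while True:
        g = minimum_spanning_network(vectors, epsilon)
        drop = sorted(
            lab for lab in vectors
            if lab not in observed and g.degree(lab) <= 2
        )
        if not drop:
            break
        for lab in drop:
            del vectors[lab]

    return _finalize_network(vectors, observed, counts, groups, tuple(site_labels), epsilon)


def _finalize_network(
    vectors: dict[str, tuple[str, ...]],
    observed: frozenset[str],
    counts: Mapping[str, int] | None,
    groups: Mapping[str, Mapping[str, int]] | None,
    site_labels: tuple[str, ...],
    epsilon: int = 0,
) -> HaploNetwork:
    g = minimum_spanning_network(vectors, epsilon)
    for lab in g.nodes:
        g.nodes[lab]["kind"] = "observed" if lab in observed else "median"
        g.nodes[lab]["count"] = int(counts.get(lab, 0)) if counts else (
            1 if lab in observed else 0
        )
        if lab not in observed:
            g.nodes[lab]["count"] = 0
        if groups and lab in groups:
            g.nodes[lab]["group"] = ",".join(
                f"{k}:{v}" for k, v in sorted(groups[lab].items())
            )
    for u, v, data in g.edges(data=True):
        diff = [
            site_labels[i] if i < len(site_labels) else str(i)
            for i, (a, b) in enumerate(zip(vectors[u], vectors[v]))
            if a != b
        ]
        data["sites"] = ",".join(diff)
    return HaploNetwork(g, vectors, observed, site_labels)


# ---------------------------------------------------------------------------
# MP pruning
# ---------------------------------------------------------------------------

def _edges_in_some_mst(g: nx.Graph) -> set[tuple[str, str]]:
    """Edges lying on at least one minimum spanning tree of *g*.

    An edge is MST-admissible iff its endpoints are disconnected in the
    subgraph of strictly lighter edges (cut property with ties).
    """
    keep: set[tuple[str, str]] = set()
    for u, v, data in g.edges(data=True):
        lighter = nx.Graph()
        lighter.add_nodes_from(g.nodes)
        lighter.add_edges_from(
            (a, b) for a, b, d2 in g.edges(data=True) if d2["length"] < data["length"]
        )
        if not nx.has_path(lighter, u, v):
            keep.add(tuple(sorted((u, v))))
    return keep


def mp_prune(net: HaploNetwork, exact_limit: int = 12) -> HaploNetwork:
    """Keep only links and medians on some minimum-length spanning tree of
    the observed haplotypes.

    Up to *exact_limit* nodes every subset of median vectors is tried and the
    union of all minimum spanning trees over the optimal subsets is retained.
    Larger networks fall back to iterative deletion of links on no minimum
    spanning tree and of degree-<=2 medians, in deterministic label order.
    """
    g = net.graph
    medians = net.medians
    if g.number_of_nodes() <= exact_limit:
        best_w = None
        optimal: list[nx.Graph] = []
        for r in range(len(medians) + 1):
            for subset in itertools.combinations(medians, r):
                nodes = set(net.observed) | set(subset)
                sub = g.subgraph(nodes)
                if len(sub) != len(nodes) or not nx.is_connected(sub):
                    continue
                w = sum(
                    d["length"]
                    for _, _, d in nx.minimum_spanning_tree(sub, weight="length").edges(
                        data=True
                    )
                )
                if best_w is None or w < best_w - 1e-9:
                    best_w, optimal = w, [sub]
                elif abs(w - best_w) <= 1e-9:
                    optimal.append(sub)
        keep_edges: set[tuple[str, str]] = set()
        for sub in optimal:
            keep_edges |= _edges_in_some_mst(sub)
        pruned = nx.Graph()
        used_nodes = set(net.observed) | {n for e in keep_edges for n in e}
        for n in used_nodes:
            pruned.add_node(n, **g.nodes[n])
        for u, v in keep_edges:
            pruned.add_edge(u, v, **g.get_edge_data(u, v))
    else:
        pruned = g.copy()
        changed = True
        while changed:
            changed = False
            admissible = _edges_in_some_mst(pruned)
            for u, v in sorted(tuple(sorted(e)) for e in pruned.edges):
                if (u, v) not in admissible:
                    pruned.remove_edge(u, v)
                    changed = True
            for m in sorted(set(pruned.nodes) - set(net.observed)):
                if pruned.degree(m) <= 2:
                    h = pruned.copy()
                    h.remove_node(m)
                    if h.number_of_nodes() == 0 or nx.is_connected(h):
                        pruned = h
                        changed = True
    vectors = {lab: net.vectors[lab] for lab in pruned.nodes}
    return HaploNetwork(pruned, vectors, net.observed, net.site_labels)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_network(
    net: HaploNetwork, prefix: str | Path, header_lines: Sequence[str] = ()
) -> tuple[Path, Path]:
    """Write the network as an edge-list TSV and a GML file.

    Returns ``(edges_path, gml_path)``.  Ordering is deterministic: edges
    sorted by (node1, node2).
    """
    prefix = Path(prefix)
    edges_path = prefix.with_suffix(".edges.tsv")
    gml_path = prefix.with_suffix(".gml")
    with open(edges_path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("node1\tnode2\tlength\tsites\n")
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
            data = net.graph.get_edge_data(u, v)
            fh.write(f"{u}\t{v}\t{data['length']:g}\t{data.get('sites', '')}\n")
    gml = net.graph.copy()
    for lab in gml.nodes:
        gml.nodes[lab]["vector"] = "".join(
            c if len(c) == 1 else f"[{c}]" for c in net.vectors[lab]
        )
    nx.write_gml(gml, str(gml_path))
    return edges_path, gml_path
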