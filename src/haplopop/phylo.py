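"""Kimura 2-parameter distances, neighbor-joining and bootstrap support.

Distances are computed between haplotypes (collapsed sequences) by default,
matching the usual presentation of control-region trees. The NJ
implementation is Saitou & Nei's agglomeration with the Studier-Keppler
Q-criterion and a lexicographic tie-break so results are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .alignment import Alignment, TRANSITION_PAIRS


class SaturationError(ValueError):
    """K2P distance undefined (log argument non-positive) for a pair."""


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(d) != 0).any():
            raise ValueError("distance matrix diagonal must be zero")

    def to_phylip(self) -> str:
        lines = [f" {len(self.labels)}"]
        for lab, row in zip(self.labels, self.d):
            lines.append(lab + "  " + " ".join(f"{x:.6f}" for x in row))
        return "\n".join(lines) + "\n"


@dataclass
class Tree:
    """Unrooted tree as a weighted graph; leaves carry a ``label`` attribute."""

    graph: nx.Graph
    negative_branches_truncated: bool = False
    supports: dict[frozenset, float] = field(default_factory=dict)

    def leaves(self) -> list[int]:
        return [n for n, deg in self.graph.degree if self.graph.nodes[n].get("label")]

    def leaf_labels(self) -> list[str]:
        return sorted(self.graph.nodes[n]["label"] for n in self.leaves())

    def path_length(self, label_a: str, label_b: str) -> float:
        idx = {self.graph.nodes[n].get("label"): n for n in self.graph.nodes}
        return nx.shortest_path_length(
            self.graph, idx[label_a], idx[label_b], weight="length"
        )

    def bipartitions(self) -> dict[frozenset, tuple[int, int]]:
        """Map each internal edge to the canonical leaf-label set it splits off.

        Canonical side is the one *not* containing the alphabetically first
        leaf label, so bipartitions compare across trees.
        """
        labels = self.leaf_labels()
        if not labels:
            return {}
        anchor = labels[0]
        out: dict[frozenset, tuple[int, int]] = {}
        for u, v in self.graph.edges:
            if self.graph.degree[u] == 1 or self.graph.degree[v] == 1:
                continue
            g = self.graph.copy()
            g.remove_edge(u, v)
            side_v = {
                self.graph.nodes[n]["label"]
                for n in nx.node_connected_component(g, v)
                if self.graph.nodes[n].get("label")
            }
            if anchor in side_v:
                side_v = set(labels) - side_v
            out[frozenset(side_v)] = (u, v)
        return out


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura (1980) two-parameter distance between two aligned sequences."""
    L = len(seq_a)
    ts = tv = 0
    for a, b in zip(seq_a, seq_b):
        if a == b:
            continue
        if frozenset((a, b)) in TRANSITION_PAIRS:
            ts += 1
        else:
            tv += 1
    P, Q = ts / L, tv / L
    w1, w2 = 1.0 - 2 * P - Q, 1.0 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P undefined: P={P:.4f}, Q={Q:.4f} (sequences too diverged)"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_matrix(aln: Alignment) -> DistanceMatrix:
    """Pairwise K2P distances between the sequences of a (haplotype) alignment."""
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    n = aln.n
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = k2p_distance(aln.seqs[i], aln.seqs[j])
            except SaturationError as err:
                raise SaturationError(
                    f"pair ({aln.ids[i]!r}, {aln.ids[j]!r}): {err}"
                ) from None
    return DistanceMatrix(tuple(aln.ids), d)


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with deterministic lexicographic tie-breaks.

    Negative branch lengths are truncated to zero and flagged on the returned
    tree. For 2 taxa the trivial single edge is returned.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    g = nx.Graph()
    node_of = {}
    for k, lab in enumerate(dm.labels):
        g.add_node(k, label=lab)
        node_of[lab] = k
    truncated = False
    if n == 2:
        g.add_edge(0, 1, length=max(float(dm.d[0, 1]), 0.0))
        return Tree(g, truncated)

    active = list(range(n))  # graph node ids
    # sort key: the smallest leaf label under each active node, for tie-breaks
    sort_key = {k: dm.labels[k] for k in range(n)}
    D = {(i, j): float(dm.d[i, j]) for i in range(n) for j in range(n)}
    next_id = n

    def dist(a, b):
        return D[(a, b)] if (a, b) in D else D[(b, a)]

    while len(active) > 3:
        m = len(active)
        r = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                a, b = active[ii], active[jj]
                q = (m - 2) * dist(a, b) - r[a] - r[b]
                key = tuple(sorted((sort_key[a], sort_key[b])))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and key < best[1]
                ):
                    best = (q, key, a, b)
        _, _, a, b = best
        la = 0.5 * dist(a, b) + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dist(a, b) - la
        if la < 0 or lb < 0:
            truncated = True
        u = next_id
        next_id += 1
        g.add_node(u)
        g.add_edge(a, u, length=max(la, 0.0))
        g.add_edge(b, u, length=max(lb, 0.0))
        for c in active:
            if c in (a, b):
                continue
            D[(u, c)] = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
        active = [c for c in active if c not in (a, b)] + [u]
        sort_key[u] = min(sort_key[a], sort_key[b])

    a, b, c = active
    u = next_id
    g.add_node(u)
    la = 0.5 * (dist(a, b) + dist(a, c) - dist(b, c))
    lb = 0.5 * (dist(a, b) + dist(b, c) - dist(a, c))
    lc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
    if min(la, lb, lc) < 0:
        truncated = True
    for node, ln in ((a, la), (b, lb), (c, lc)):
        g.add_edge(node, u, length=max(ln, 0.0))
    return Tree(g, truncated)


def bootstrap_support(
    aln: Alignment, reps: int = 1000, seed: int | None = None
) -> tuple[Tree, int]:
    """NJ tree with bootstrap support on its internal bipartitions.

    Alignment columns are resampled with replacement; each replicate gets its
    own K2P + NJ tree; support for an internal edge of the point-estimate tree
    is the percentage of usable replicates containing the same bipartition.
    Replicates with an undefined K2P distance are dropped (and counted in the
    returned drop count).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    tree = neighbor_joining(k2p_matrix(aln))
    arr0 = aln.to_array()
    if all(len(np.unique(col)) == 1 for col in arr0.T):
        import warnings

        warnings.warn("zero-variation alignment: bootstrap supports undefined")
        tree.supports = {
            bp: float("nan")
            for bp in tree.bipartitions()
            if 1 < len(bp) < len(aln.ids) - 1
        }
        return tree, 0
    biparts = {
        bp for bp in tree.bipartitions() if 1 < len(bp) < len(aln.ids) - 1
    }
    counts = {bp: 0 for bp in biparts}
    arr = aln.to_array()
    dropped = 0
    used = 0
    for _ in range(reps):
        cols = rng.integers(0, aln.length, size=aln.length)
        rep_aln = Alignment.from_array(aln.ids, arr[:, cols])
        try:
            rep_tree = neighbor_joining(k2p_matrix(rep_aln))
        except SaturationError:
            dropped += 1
            continue
        used += 1
        rep_biparts = set(rep_tree.bipartitions())
        for bp in biparts & rep_biparts:
            counts[bp] += 1
    if used == 0:
        tree.supports = {bp: float("nan") for bp in biparts}
    else:
        tree.supports = {bp: 100.0 * c / used for bp, c in counts.items()}
    return tree, dropped


def write_newick(tree: Tree, include_support: bool = True) -> str:
    """Serialize an unrooted tree, supports as internal node labels."""
    g = tree.graph
    leaves = tree.leaves()
    if len(leaves) == 1:
        return f"{g.nodes[leaves[0]]['label']};"
    if len(leaves) == 2 and g.number_of_nodes() == 2:
        a, b = leaves
        ln = g.edges[a, b]["length"]
        return (
            f"({g.nodes[a]['label']}:{0.0:.10g},"
            f"{g.nodes[b]['label']}:{ln:.17g});"
        )
    # root at an internal node adjacent to the alphabetically first leaf
    first_leaf = min(leaves, key=lambda n: g.nodes[n]["label"])
    root = next(iter(g.neighbors(first_leaf)))
    biparts = tree.bipartitions() if tree.supports else {}
    edge_support = {}
    for bp, (u, v) in biparts.items():
        if bp in tree.supports:
            edge_support[frozenset((u, v))] = tree.supports[bp]

    def emit(node, parent):
        children = [c for c in g.neighbors(node) if c != parent]
        label = g.nodes[node].get("label")
        if not children:
            return label
        inner = ",".join(
            f"{emit(c, node)}:{g.edges[node, c]['length']:.17g}" for c in children
        )
        sup = edge_support.get(frozenset((node, parent))) if parent is not None else None
        sup_str = (
            f"{sup:.4g}" if include_support and sup is not None and not math.isnan(sup)
            else ""
        )
        return f"({inner}){sup_str}"

    return emit(root, None) + ";"


def read_newick(text: str) -> Tree:
    """Parse a newick string (via dendropy) back into a :class:`Tree`."""
    import dendropy

    dtree = dendropy.Tree.get(data=text, schema="newick")
    g = nx.Graph()
    ids = {}
    counter = [0]

    def nid(node):
        if node not in ids:
            ids[node] = counter[0]
            counter[0] += 1
            label = node.taxon.label if node.taxon else None
            if label:
                g.add_node(ids[node], label=label.replace(" ", "_"))
            else:
                g.add_node(ids[node])
        return ids[node]

    for edge in dtree.preorder_edge_iter():
        if edge.tail_node is None:
            nid(edge.head_node)
            continue
        u, v = nid(edge.tail_node), nid(edge.head_node)
        g.add_edge(u, v, length=edge.length if edge.length is not None else 0.0)
    # suppress the artificial degree-2 root introduced by rooting
    for node in [n for n, deg in g.degree if deg == 2 and not g.nodes[n].get("label")]:
        a, b = list(g.neighbors(node))
        ln = g.edges[node, a]["length"] + g.edges[node, b]["length"]
        g.remove_node(node)
        g.add_edge(a, b, length=ln)
    tree = Tree(g)
    return tree
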