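"""Median-joining haplotype networks.

Bandelt-style construction: repeatedly build an epsilon-relaxed minimum
spanning network (MSN) over the current node set, propose quasi-median
(per-site majority) vectors for triplets linked in that network, keep the
ones that shorten the minimum spanning tree, and finally prune median
vectors that are no longer needed to connect the observed haplotypes.

Only segregating columns are retained internally, so edge weights are
substitution counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .alignment import HaplotypeTable


@dataclass
class HaplotypeNetwork:
    """Graph of observed haplotypes plus inferred median vectors.

    Node attributes: ``seq`` (condensed, variable sites only), ``observed``
    (bool), ``freqs`` (per-population carrier counts; all-zero for medians),
    ``label``. Edge attribute ``weight`` is the substitution count.
    """

    graph: nx.Graph
    populations: tuple[str, ...]
    variable_columns: tuple[int, ...]

    @property
    def total_length(self) -> int:
        return int(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))

    def n_medians(self) -> int:
        return sum(1 for _, d in self.graph.nodes(data=True) if not d["observed"])

    def to_edge_table(self):
        import pandas as pd

        rows = [
            {"from": u, "to": v, "substitutions": d["weight"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows)

    def to_node_table(self):
        import pandas as pd

        rows = []
        for node, d in self.graph.nodes(data=True):
            row = {"node": node, "observed": d["observed"]}
            for pop, c in zip(self.populations, d["freqs"]):
                row[pop] = int(c)
            rows.append(row)
        return pd.DataFrame(rows)

    def write_gml(self, path) -> None:
        g = nx.Graph()
        for node, d in self.graph.nodes(data=True):
            g.add_node(
                node,
                observed=int(d["observed"]),
                frequency=int(sum(d["freqs"])),
                seq=d["seq"],
            )
        for u, v, d in self.graph.edges(data=True):
            g.add_edge(u, v, weight=int(d["weight"]))
        nx.write_gml(g, str(path))


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _to_array(seqs: list[str]) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(
        len(seqs), -1
    )


def _distance_matrix(seqs: list[str]) -> np.ndarray:
    arr = _to_array(seqs)
    return (arr[:, None, :] != arr[None, :, :]).sum(axis=2)


def _mst_length_from_d(d: np.ndarray) -> int:
    from scipy.sparse.csgraph import minimum_spanning_tree

    # offset by 1 so zero distances survive the sparse representation
    return int(minimum_spanning_tree(d + 1).sum()) - (d.shape[0] - 1)


def _bottlenecks(d: np.ndarray) -> np.ndarray:
    """Minimax path weight between every pair, via the MST of the full graph."""
    n = d.shape[0]
    g = nx.Graph()
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(i, j, weight=int(d[i, j]))
    mst = nx.minimum_spanning_tree(g, weight="weight")
    bn = np.zeros((n, n), dtype=int)
    for i in range(n):
        # DFS over MST tracking max edge weight on the path
        stack = [(i, -1, 0)]
        while stack:
            node, parent, mx = stack.pop()
            bn[i, node] = mx
            for nb in mst.neighbors(node):
                if nb != parent:
                    stack.append((nb, node, max(mx, mst.edges[node, nb]["weight"])))
    return bn


def minimum_spanning_network(
    seqs: list[str], epsilon: int = 0, d: np.ndarray | None = None
) -> nx.Graph:
    """Epsilon-relaxed MSN: edge (u, v) kept iff d(u, v) <= bottleneck(u, v) + eps.

    With epsilon = 0 this is the union of all minimum spanning trees.
    """
    if d is None:
        d = _distance_matrix(seqs)
    bn = _bottlenecks(d)
    g = nx.Graph()
    g.add_nodes_from(range(len(seqs)))
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if d[i, j] <= bn[i, j] + epsilon:
                g.add_edge(i, j, weight=int(d[i, j]))
    return g


def _mst_length(seqs: list[str]) -> int:
    d = _distance_matrix(seqs)
    g = nx.Graph()
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            g.add_edge(i, j, weight=int(d[i, j]))
    mst = nx.minimum_spanning_tree(g, weight="weight")
    return int(sum(dd["weight"] for _, _, dd in mst.edges(data=True)))


def _quasi_medians(a: str, b: str, c: str, cap: int) -> list[str]:
    """Per-site majority consensus; three-way ties expand to all combinations."""
    fixed: list[str | tuple] = []
    n_combo = 1
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            fixed.append(x)
        elif y == z:
            fixed.append(y)
        else:
            fixed.append((x, y, z))
            n_combo *= 3
        if n_combo > cap:
            return []
    out = []
    options = [(s,) if isinstance(s, str) else s for s in fixed]
    for combo in itertools.product(*options):
        out.append("".join(combo))
    return out


def build_mj_network(
    haps: HaplotypeTable,
    epsilon: int = 0,
    median_cap: int = 1000,
) -> HaplotypeNetwork:
    """Median-joining network of the observed haplotypes.

    Parameters
    ----------
    haps
        Collapsed haplotypes with per-population counts.
    epsilon
        Relaxation of the MSN connection criterion (0, the customary
        default, keeps only union-of-MST links).
    median_cap
        Upper bound on tie-expanded quasi-median candidates per triplet; a
        triplet exceeding it contributes no candidates (warning case for
        extremely homoplasic data).
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if haps.n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    for seq in haps.haplotypes:
        bad = set(seq) - set("ACGT")
        if bad:
            raise ValueError(f"non-nucleotide states in haplotypes: {sorted(bad)}")

    arr = np.array([list(s) for s in haps.haplotypes], dtype="U1")
    variable = [
        j for j in range(arr.shape[1]) if len(np.unique(arr[:, j])) > 1
    ]
    condensed = ["".join(arr[i, variable]) for i in range(arr.shape[0])]

    observed = list(dict.fromkeys(condensed))
    nodes = list(observed)
    d = _distance_matrix(nodes)
    # iterate: MSN -> quasi-medians -> keep those shortening the MST
    for _ in range(100):  # fixpoint in practice long before this
        msn = minimum_spanning_network(nodes, epsilon, d=d)
        base_len = _mst_length_from_d(d)
        present = set(nodes)
        candidates: dict[str, None] = {}
        for u in msn.nodes:
            nbrs = sorted(msn.neighbors(u))
            for v, w in itertools.combinations(nbrs, 2):
                for med in _quasi_medians(nodes[u], nodes[v], nodes[w], median_cap):
                    if med not in present:
                        candidates.setdefault(med, None)
        arr = _to_array(nodes)
        # score every candidate against the current MST, then admit greedily
        # against the growing set so redundant medians are not piled up
        scored = []
        for med in candidates:
            mrow = (arr != _to_array([med])).sum(axis=1)
            k = len(nodes)
            aug = np.zeros((k + 1, k + 1), dtype=int)
            aug[:k, :k] = d
            aug[k, :k] = aug[:k, k] = mrow
            length = _mst_length_from_d(aug)
            if length < base_len:
                scored.append((length, med))
        if not scored:
            break
        scored.sort(key=lambda t: (t[0], t[1]))
        cur_nodes, cur_d = list(nodes), d
        cur_len = base_len
        for _, med in scored:
            marr = _to_array([med])
            mrow = (_to_array(cur_nodes) != marr).sum(axis=1)
            k = len(cur_nodes)
            aug = np.zeros((k + 1, k + 1), dtype=int)
            aug[:k, :k] = cur_d
            aug[k, :k] = aug[:k, k] = mrow
            length = _mst_length_from_d(aug)
            if length < cur_len:
                cur_nodes.append(med)
                cur_d = aug
                cur_len = length
        if len(cur_nodes) == len(nodes):
            break
        nodes, d = cur_nodes, cur_d

    # prune median vectors whose removal leaves the MST length unchanged
    changed = True
    while changed:
        changed = False
        base_len = _mst_length_from_d(d)
        obs_set = set(observed)
        for mi, med in enumerate(nodes):
            if med in obs_set:
                continue
            keep = [j for j in range(len(nodes)) if j != mi]
            if _mst_length_from_d(d[np.ix_(keep, keep)]) <= base_len:
                nodes = [nodes[j] for j in keep]
                d = d[np.ix_(keep, keep)]
                changed = True
                break

    msn = minimum_spanning_network(nodes, epsilon)
    g = nx.Graph()
    obs_index = {s: i for i, s in enumerate(observed)}
    cond_to_hap: dict[str, list[int]] = {}
    for hi, s in enumerate(condensed):
        cond_to_hap.setdefault(s, []).append(hi)
    n_pops = len(haps.populations)
    median_counter = 0
    names = {}
    for ni, seq in enumerate(nodes):
        if seq in obs_index:
            hap_rows = cond_to_hap[seq]
            freqs = haps.counts[hap_rows].sum(axis=0)
            label = haps.labels[hap_rows[0]] if haps.labels else f"H{hap_rows[0] + 1}"
            is_obs = True
        else:
            freqs = np.zeros(n_pops, dtype=int)
            median_counter += 1
            label = f"mv{median_counter}"
            is_obs = False
        names[ni] = label
        g.add_node(label, seq=seq, observed=is_obs, freqs=tuple(int(x) for x in freqs))
    for u, v, d in msn.edges(data=True):
        g.add_edge(names[u], names[v], weight=int(d["weight"]))
    return HaplotypeNetwork(g, haps.populations, tuple(variable))
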