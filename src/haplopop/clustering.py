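"""Model-based clustering of sequences into panmictic groups.

Each cluster is modelled by independent per-site base frequencies with a
symmetric Dirichlet prior; the score of a partition is the product over
clusters and sites of the Dirichlet-multinomial marginal likelihood of the
cluster's base counts. A greedy single-move search with seeded random
restarts maximises the score over partitions for each candidate number of
clusters k, and the best-scoring k wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .alignment import Alignment

DEFAULT_ALPHA = 0.25  # symmetric prior mass per base

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class ClusterResult:
    k: int
    labels: dict[str, int]
    log_marginal: float
    membership_probs: np.ndarray  # individuals x k, rows sum to 1
    replicate_scores: dict[tuple[int, int], float]
    ids: tuple[str, ...]


def _one_hot(aln: Alignment) -> np.ndarray:
    arr = aln.to_array()
    out = np.zeros((aln.n, aln.length, 4), dtype=np.int32)
    for base, b in _BASE_INDEX.items():
        out[:, :, b] = arr == base
    return out


def _cluster_logml(counts: np.ndarray, alpha: float) -> np.ndarray:
    """Dirichlet-multinomial log marginal for base-count arrays (..., S, 4)."""
    counts = np.asarray(counts, dtype=float)
    a0 = 4.0 * alpha
    n = counts.sum(axis=-1)
    per_site = (
        gammaln(a0)
        - gammaln(a0 + n)
        + (gammaln(alpha + counts) - gammaln(alpha)).sum(axis=-1)
    )
    return per_site.sum(axis=-1)


def dirichlet_multinomial_score(
    partition, aln: Alignment, alpha: float = DEFAULT_ALPHA
) -> float:
    """Log marginal likelihood of a partition (id -> cluster label).

    Empty clusters contribute nothing; the score is invariant to cluster
    relabeling and to the order of individuals.
    """
    x = _one_hot(aln)
    clusters: dict = {}
    for i, sid in enumerate(aln.ids):
        clusters.setdefault(partition[sid], []).append(i)
    total = 0.0
    for members in clusters.values():
        total += float(_cluster_logml(x[members].sum(axis=0), alpha))
    return total


def _greedy_search(
    x: np.ndarray, k: int, rng: np.random.Generator, alpha: float, max_iter: int = 500
) -> tuple[np.ndarray, float]:
    n = x.shape[0]
    z = rng.integers(0, k, size=n)
    C = np.zeros((k,) + x.shape[1:], dtype=np.int64)
    for c in range(k):
        C[c] = x[z == c].sum(axis=0)
    f = _cluster_logml(C, alpha)  # shape (k,)

    for _ in range(max_iter):
        # score of each source cluster with one member removed
        removed = np.empty(n)
        for c in range(k):
            members = np.flatnonzero(z == c)
            if len(members):
                removed[members] = _cluster_logml(C[c] - x[members], alpha)
        # score of each target cluster with each individual added
        added = np.empty((n, k))
        for c in range(k):
            added[:, c] = _cluster_logml(C[c][None] + x, alpha)
        delta = removed[:, None] + added - f[z][:, None] - f[None, :]
        delta[np.arange(n), z] = 0.0
        i, c_new = np.unravel_index(np.argmax(delta), delta.shape)
        if delta[i, c_new] <= 1e-9:
            break
        c_old = z[i]
        C[c_old] -= x[i]
        C[c_new] += x[i]
        f[c_old] = _cluster_logml(C[c_old], alpha)
        f[c_new] = _cluster_logml(C[c_new], alpha)
        z[i] = c_new
    return z, float(f.sum())


def _membership_probs(
    x: np.ndarray, z: np.ndarray, k: int, alpha: float
) -> np.ndarray:
    """Leave-self-out predictive probability of each individual per cluster."""
    n = x.shape[0]
    C = np.zeros((k,) + x.shape[1:], dtype=np.int64)
    for c in range(k):
        C[c] = x[z == c].sum(axis=0)
    logp = np.empty((n, k))
    for c in range(k):
        base = C[c][None] - np.where((z == c)[:, None, None], x, 0)
        logp[:, c] = _cluster_logml(base + x, alpha) - _cluster_logml(base, alpha)
    logp -= logp.max(axis=1, keepdims=True)
    probs = np.exp(logp)
    probs /= probs.sum(axis=1, keepdims=True)
    return probs


def fit_clusters(
    aln: Alignment,
    k_max: int = 10,
    replicates: int = 5,
    seed: int | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> ClusterResult:
    """Greedy Dirichlet-multinomial clustering over k = 1..k_max.

    For each k, `replicates` seeded random restarts of the greedy
    single-move search are run; the partition with the highest log marginal
    likelihood over all k and restarts is returned, along with every
    replicate's score. Cluster labels are renumbered 0..k_eff-1 by first
    occurrence; empty clusters are dropped.
    """
    if aln.n < 2:
        raise ValueError("clustering needs at least 2 sequences")
    x = _one_hot(aln)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(k_max * replicates)
    best = None
    replicate_scores: dict[tuple[int, int], float] = {}
    idx = 0
    for k in range(1, k_max + 1):
        for rep in range(replicates):
            rng = np.random.default_rng(child_seeds[idx])
            idx += 1
            z, score = _greedy_search(x, k, rng, alpha)
            replicate_scores[(k, rep)] = score
            if best is None or score > best[1] + 1e-12:
                best = (z.copy(), score, k)
    z, score, _ = best
    # renumber occupied clusters by first occurrence
    remap: dict[int, int] = {}
    for c in z:
        remap.setdefault(int(c), len(remap))
    z = np.array([remap[int(c)] for c in z])
    k_eff = len(remap)
    probs = _membership_probs(x, z, k_eff, alpha)
    return ClusterResult(
        k=k_eff,
        labels={sid: int(c) for sid, c in zip(aln.ids, z)},
        log_marginal=score,
        membership_probs=probs,
        replicate_scores=replicate_scores,
        ids=aln.ids,
    )


def assignment_table(result: ClusterResult, pm=None):
    """Long-format assignment table (id, population, cluster, per-cluster probs)."""
    import pandas as pd

    rows = []
    for i, sid in enumerate(result.ids):
        row = {
            "id": sid,
            "population": pm.assignment[sid] if pm is not None else "",
            "cluster": result.labels[sid],
        }
        for c in range(result.k):
            row[f"p_cluster{c}"] = result.membership_probs[i, c]
        rows.append(row)
    return pd.DataFrame(rows)
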