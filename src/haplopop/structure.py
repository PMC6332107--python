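"""AMOVA, pairwise fixation indices, corrected divergence Da and Mantel IBD.

The one-level AMOVA partitions squared inter-individual molecular distances
(by default raw pairwise nucleotide difference counts) into among- and
within-population components:

    SS_total  = (1/N) * sum_{i<j} delta_ij^2
    SS_within = sum_pop (1/n_p) * sum_{i<j in pop} delta_ij^2
    Vb        = SS_within / (N - k)
    Va        = (SS_among/(k-1) - Vb) / n'   with  n' = (N - sum n_p^2/N)/(k-1)
    Phi_ST    = Va / (Va + Vb)

Permutation p-values shuffle individuals across populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment, PopulationMap
from .diversity import pairwise_difference_matrix
from .phylo import DistanceMatrix


@dataclass(frozen=True)
class AmovaResult:
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    Va: float
    Vb: float
    pct_among: float
    pct_within: float
    phi_st: float
    p: float | None = None
    undefined: bool = False


@dataclass
class PairwiseStats:
    populations: tuple[str, ...]
    fst: np.ndarray | None = None
    phist: np.ndarray | None = None
    da: np.ndarray | None = None
    p_fst: np.ndarray | None = None
    p_phist: np.ndarray | None = None
    significant: np.ndarray | None = None
    flags: dict = field(default_factory=dict)


def amova_from_ss(
    ss_among: float, ss_within: float, sizes
) -> AmovaResult:
    """Variance components and Phi_ST from printed sums of squares and sizes.

    This is the desk calculation: given SS_among with df = k-1, SS_within
    with df = N-k and the k sample sizes, recover Vb, Va, the percentages of
    variation and the fixation index.
    """
    sizes = np.asarray(sizes, dtype=float)
    k = len(sizes)
    N = sizes.sum()
    df_among = k - 1
    df_within = int(N - k)
    Vb = ss_within / df_within
    n_prime = (N - (sizes**2).sum() / N) / df_among
    Va = (ss_among / df_among - Vb) / n_prime
    total = Va + Vb
    phi = Va / total if total > 0 else float("nan")
    return AmovaResult(
        df_among=df_among,
        df_within=df_within,
        ss_among=ss_among,
        ss_within=ss_within,
        Va=Va,
        Vb=Vb,
        pct_among=100.0 * Va / total if total > 0 else float("nan"),
        pct_within=100.0 * Vb / total if total > 0 else float("nan"),
        phi_st=phi,
        undefined=not total > 0,
    )


def _amova_ss(d2: np.ndarray, groups: list[np.ndarray]) -> tuple[float, float]:
    N = d2.shape[0]
    iu = np.triu_indices(N, k=1)
    ss_total = d2[iu].sum() / N
    ss_within = 0.0
    for idx in groups:
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += np.triu(sub, k=1).sum() / len(idx)
    return ss_total - ss_within, ss_within


def amova(
    aln: Alignment,
    pm: PopulationMap,
    permutations: int = 10000,
    seed: int | None = None,
    distance: str = "differences",
) -> AmovaResult:
    """One-level AMOVA with a permutation test on Phi_ST.

    ``distance='differences'`` uses raw pairwise nucleotide difference counts
    as the squared inter-individual distance (the haplotypic convention);
    ``'squared_k2p'`` uses squared K2P distances instead.
    """
    pm.validate_against(aln)
    pops = pm.populations
    if len(pops) < 2:
        raise ValueError("AMOVA requires at least 2 populations")
    if distance == "differences":
        d2 = pairwise_difference_matrix(aln).astype(float)
    elif distance == "squared_k2p":
        from .phylo import k2p_matrix

        d2 = k2p_matrix(aln).d ** 2
    else:
        raise ValueError(f"unknown distance {distance!r}")

    id_index = {sid: i for i, sid in enumerate(aln.ids)}
    groups = [
        np.array([id_index[sid] for sid in pm.members(pop)]) for pop in pops
    ]
    sizes = np.array([len(g) for g in groups], dtype=float)
    N, k = int(sizes.sum()), len(pops)
    ss_among, ss_within = _amova_ss(d2, groups)
    res = amova_from_ss(ss_among, ss_within, sizes)
    if res.undefined or permutations < 1:
        return res

    rng = np.random.default_rng(seed)
    labels = np.concatenate([np.full(len(g), j) for j, g in enumerate(groups)])
    order = np.concatenate(groups)
    count = 1  # observed included
    for _ in range(permutations):
        perm = rng.permutation(labels)
        perm_groups = [order[perm == j] for j in range(k)]
        sa, sw = _amova_ss(d2, perm_groups)
        perm_res = amova_from_ss(sa, sw, sizes)
        if not perm_res.undefined and perm_res.phi_st >= res.phi_st - 1e-12:
            count += 1
    p = count / (permutations + 1)
    return AmovaResult(
        **{**res.__dict__, "p": p}
    )


def weir_cockerham_fst(counts_x: np.ndarray, counts_y: np.ndarray) -> float:
    """Weir & Cockerham's theta for two haploid samples.

    Each haplotype is treated as an allele at a single haploid locus; the
    per-allele among/within components are summed over alleles.
    """
    counts_x = np.asarray(counts_x, dtype=float)
    counts_y = np.asarray(counts_y, dtype=float)
    n_i = np.array([counts_x.sum(), counts_y.sum()])
    r = 2
    n_bar = n_i.mean()
    n_total = n_i.sum()
    n_c = (n_total - (n_i**2).sum() / n_total) / (r - 1)
    p = np.vstack([counts_x / n_i[0], counts_y / n_i[1]])  # pop x allele
    p_bar = (n_i[:, None] * p).sum(axis=0) / n_total
    # per-allele mean squares (haploid analogue of W&C 1984)
    msp = (n_i[:, None] * (p - p_bar) ** 2).sum(axis=0) / (r - 1)
    msg = (n_i[:, None] * p * (1 - p)).sum(axis=0) / (n_total - r)
    a = (msp - msg) / n_c
    b = msg
    denom = (a + b).sum()
    if denom == 0:
        return 0.0
    return float(a.sum() / denom)


def _pair_tables(aln: Alignment, pm: PopulationMap):
    from .alignment import collapse_haplotypes

    haps = collapse_haplotypes(aln, pm)
    return haps


def pairwise_fst(
    aln: Alignment,
    pm: PopulationMap,
    mode: str = "frequency",
    permutations: int = 10000,
    seed: int | None = None,
) -> PairwiseStats:
    """Pairwise FST (haplotype-frequency Weir-Cockerham) or Phi_ST (distance).

    Permutation p-values reshuffle individuals between the two populations of
    each comparison; the observed value is included in numerator and
    denominator.
    """
    pm.validate_against(aln)
    pops = pm.populations
    k = len(pops)
    rng = np.random.default_rng(seed)
    stat = np.zeros((k, k))
    pmat = np.full((k, k), np.nan)
    flags = {}

    d2 = pairwise_difference_matrix(aln).astype(float)
    id_index = {sid: i for i, sid in enumerate(aln.ids)}
    haps = _pair_tables(aln, pm)

    def frequency_stat(idx_x, idx_y):
        # haplotype counts restricted to the pair, recollapsed on the pair only
        sub_ids = [aln.ids[i] for i in np.concatenate([idx_x, idx_y])]
        sub = aln.subset(sub_ids)
        labels = ["X"] * len(idx_x) + ["Y"] * len(idx_y)
        sub_pm = PopulationMap(dict(zip(sub_ids, labels)))
        from .alignment import collapse_haplotypes

        t = collapse_haplotypes(sub, sub_pm)
        cx = t.counts[:, list(t.populations).index("X")]
        cy = t.counts[:, list(t.populations).index("Y")]
        return weir_cockerham_fst(cx, cy)

    def distance_stat(idx_x, idx_y):
        groups = [np.asarray(idx_x), np.asarray(idx_y)]
        sizes = np.array([len(g) for g in groups], dtype=float)
        sa, sw = _amova_ss(d2, groups)
        res = amova_from_ss(sa, sw, sizes)
        return res.phi_st if not res.undefined else 0.0

    fn = frequency_stat if mode == "frequency" else distance_stat
    if mode not in ("frequency", "distance"):
        raise ValueError(f"unknown mode {mode!r}")

    member_idx = {
        pop: np.array([id_index[sid] for sid in pm.members(pop)]) for pop in pops
    }
    for a in range(k):
        for b in range(a + 1, k):
            ix, iy = member_idx[pops[a]], member_idx[pops[b]]
            if min(len(ix), len(iy)) < 2:
                flags[(pops[a], pops[b])] = "population of size < 2"
            obs = fn(ix, iy)
            stat[a, b] = stat[b, a] = obs
            if permutations >= 1:
                pool = np.concatenate([ix, iy])
                count = 1
                for _ in range(permutations):
                    perm = rng.permutation(pool)
                    val = fn(perm[: len(ix)], perm[len(ix):])
                    if val >= obs - 1e-12:
                        count += 1
                pv = count / (permutations + 1)
                pmat[a, b] = pmat[b, a] = pv
    out = PairwiseStats(populations=pops, flags=flags)
    if mode == "frequency":
        out.fst, out.p_fst = stat, pmat
    else:
        out.phist, out.p_phist = stat, pmat
    return out


def corrected_da(aln: Alignment, pm: PopulationMap) -> PairwiseStats:
    """Corrected average pairwise difference between populations:

        Da = PiXY - (PiX + PiY)/2

    where PiXY is the mean cross-population pairwise difference count and
    PiX/PiY the within-population means. Negative values are reported as
    computed.
    """
    pm.validate_against(aln)
    pops = pm.populations
    d = pairwise_difference_matrix(aln).astype(float)
    id_index = {sid: i for i, sid in enumerate(aln.ids)}
    idx = {p: np.array([id_index[s] for s in pm.members(p)]) for p in pops}
    for p in pops:
        if len(idx[p]) < 2:
            raise ValueError(f"population {p!r} has fewer than 2 individuals")

    def within(i):
        sub = d[np.ix_(i, i)]
        iu = np.triu_indices(len(i), k=1)
        return sub[iu].mean()

    k = len(pops)
    da = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            pixy = d[np.ix_(idx[pops[a]], idx[pops[b]])].mean()
            val = pixy - (within(idx[pops[a]]) + within(idx[pops[b]])) / 2.0
            da[a, b] = da[b, a] = val
    return PairwiseStats(populations=pops, da=da)


def bonferroni_adjust(p_matrix: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Significance flags after Bonferroni correction over the m comparisons.

    A comparison is significant iff p <= alpha / m where m is the number of
    off-diagonal upper-triangle entries (or the length of a flat array).
    """
    p = np.asarray(p_matrix, dtype=float)
    if p.ndim == 2:
        iu = np.triu_indices(p.shape[0], k=1)
        m = len(iu[0])
    else:
        m = p.size
    if m < 1:
        raise ValueError("need at least one comparison")
    return p <= alpha / m


def mantel_test(
    genetic: DistanceMatrix,
    geographic: DistanceMatrix,
    permutations: int = 10000,
    seed: int | None = None,
    method: str = "permutation",
) -> tuple[float, float, float]:
    """Mantel correlation between two distance matrices with permutation p.

    Returns (r, R^2, p). p is one-sided (greater), counts the observed
    correlation in numerator and denominator, and permutes rows/columns of
    the second matrix jointly. ``method='exact'`` enumerates all k!
    permutations (small k only) and reports the exact fraction with
    r >= r_observed.
    """
    if genetic.labels != geographic.labels:
        raise ValueError("matrices must share identical labels")
    k = len(genetic.labels)
    if k < 3:
        raise ValueError("Mantel test needs at least 3 items")
    iu = np.triu_indices(k, k=1)
    x = genetic.d[iu]
    y = geographic.d[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance distance matrix; r undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    if method == "exact":
        import itertools

        count = total = 0
        for perm in itertools.permutations(range(k)):
            perm = np.array(perm)
            yp = geographic.d[np.ix_(perm, perm)][iu]
            total += 1
            if np.corrcoef(x, yp)[0, 1] >= r_obs - 1e-12:
                count += 1
        return r_obs, r_obs**2, count / total
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    count = 1
    for _ in range(permutations):
        perm = rng.permutation(k)
        yp = geographic.d[np.ix_(perm, perm)][iu]
        r = np.corrcoef(x, yp)[0, 1]
        if r >= r_obs - 1e-12:
            count += 1
    p = count / (permutations + 1)
    return r_obs, r_obs**2, p


def great_circle_km(coords: dict[str, tuple[float, float]]) -> DistanceMatrix:
    """Great-circle distances (km) between labelled (lat, lon) points.

    A convenience for building a geographic matrix; distances along a
    coastline or shipping path must be supplied by the user instead when the
    straight-line geometry is inappropriate.
    """
    labels = tuple(coords)
    k = len(labels)
    d = np.zeros((k, k))
    R = 6371.0
    for i in range(k):
        for j in range(i + 1, k):
            la1, lo1 = (math.radians(v) for v in coords[labels[i]])
            la2, lo2 = (math.radians(v) for v in coords[labels[j]])
            h = (
                math.sin((la2 - la1) / 2) ** 2
                + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2) ** 2
            )
            d[i, j] = d[j, i] = 2 * R * math.asin(math.sqrt(h))
    return DistanceMatrix(labels, d)
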