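"""Per-population and pooled diversity indices.

Implements Nei's haplotype diversity with its sampling variance and the mean
number of pairwise nucleotide differences M with Tajima's total (stochastic +
sampling) variance; nucleotide diversity pi is M per filtered site.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import Alignment, PopulationMap, classify_sites, collapse_haplotypes


@dataclass(frozen=True)
class DiversitySummary:
    """Diversity indices for one sample of aligned sequences."""

    n: int
    S: int
    M: float
    M_sd: float
    Hd: float
    Hd_sd: float
    pi: float
    pi_sd: float
    L_used: int


def haplotype_diversity(counts, n: int | None = None) -> tuple[float, float]:
    """Nei's unbiased haplotype diversity and its standard deviation.

    Hd = n/(n-1) * (1 - sum p_i^2) with p_i the haplotype relative
    frequencies; the variance is Nei's (1987) sampling variance of
    heterozygosity:

        V(Hd) = 2/(n(n-1)) * [2(n-2)(sum p^3 - (sum p^2)^2)
                              + sum p^2 - (sum p^2)^2]
    """
    counts = np.asarray(counts, dtype=float)
    total = int(round(counts.sum()))
    if n is None:
        n = total
    elif n != total:
        raise ValueError(f"counts sum to {total}, not n={n}")
    if n < 2:
        raise ValueError("haplotype diversity requires n >= 2")
    p = counts / n
    sp2 = float((p**2).sum())
    sp3 = float((p**3).sum())
    hd = n / (n - 1) * (1.0 - sp2)
    var = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (sp3 - sp2**2) + sp2 - sp2**2)
    return hd, math.sqrt(max(var, 0.0))


def pairwise_difference_matrix(aln: Alignment) -> np.ndarray:
    """(n, n) matrix of Hamming distances (difference counts) between sequences."""
    arr = aln.to_array().view(np.uint32)
    arr = arr.reshape(aln.n, -1)
    return (arr[:, None, :] != arr[None, :, :]).sum(axis=2)


def mean_pairwise_differences(aln: Alignment) -> float:
    """Average number of differing sites over all n(n-1)/2 sequence pairs."""
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    d = pairwise_difference_matrix(aln)
    iu = np.triu_indices(aln.n, k=1)
    return float(d[iu].mean())


def _tajima_total_variance_per_site(pi: float, n: int, L: int) -> float:
    # Tajima (1983) total variance of nucleotide diversity, no recombination
    return (n + 1) / (3.0 * (n - 1) * L) * pi + (
        2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    ) * pi * pi


def pairwise_difference_stats(aln: Alignment) -> DiversitySummary:
    """M +- SD, segregating sites S and per-site diversity pi +- SD.

    SDs come from Tajima's (1983) total variance, which includes the
    evolutionary (stochastic) component and therefore scales roughly with the
    statistic itself rather than shrinking with sample size.
    """
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    n, L = aln.n, aln.length
    arr = aln.to_array()
    S = int(sum(len(np.unique(col)) > 1 for col in arr.T))
    M = mean_pairwise_differences(aln)
    pi = M / L
    var_pi = _tajima_total_variance_per_site(pi, n, L)
    pi_sd = math.sqrt(max(var_pi, 0.0))
    M_sd = pi_sd * L
    return DiversitySummary(
        n=n, S=S, M=M, M_sd=M_sd, Hd=float("nan"), Hd_sd=float("nan"),
        pi=pi, pi_sd=pi_sd, L_used=L,
    )


def diversity_summary(aln: Alignment, pm: PopulationMap | None = None) -> DiversitySummary:
    """All diversity indices for one (sub)alignment."""
    haps = collapse_haplotypes(
        aln, pm if pm is not None else PopulationMap({i: "all" for i in aln.ids})
    )
    hd, hd_sd = haplotype_diversity(haps.total_counts())
    base = pairwise_difference_stats(aln)
    return DiversitySummary(
        n=base.n, S=base.S, M=base.M, M_sd=base.M_sd,
        Hd=hd, Hd_sd=hd_sd, pi=base.pi, pi_sd=base.pi_sd, L_used=base.L_used,
    )


def diversity_table(aln: Alignment, pm: PopulationMap) -> pd.DataFrame:
    """Per-population plus pooled diversity report.

    Columns follow the conventional summary layout: N, Nh, Np, Tv/Ts,
    M +- SD, Hd +- SD, pi +- SD. One row per population and a final pooled
    row labelled ``Total``.
    """
    rows = []
    for pop in list(pm.populations) + ["Total"]:
        if pop == "Total":
            sub = aln
            sub_pm = pm
        else:
            ids = pm.members(pop)
            sub = aln.subset(ids)
            sub_pm = PopulationMap({i: pop for i in ids})
        haps = collapse_haplotypes(sub, sub_pm)
        sites = classify_sites(sub)
        summ = diversity_summary(sub, sub_pm)
        rows.append(
            {
                "population": pop,
                "N": summ.n,
                "Nh": haps.n_haplotypes,
                "Np": sites.polymorphic_sites,
                "Tv/Ts": sites.tv_ts_ratio,
                "M": summ.M,
                "M_sd": summ.M_sd,
                "Hd": summ.Hd,
                "Hd_sd": summ.Hd_sd,
                "pi": summ.pi,
                "pi_sd": summ.pi_sd,
                "S": summ.S,
                "L_used": summ.L_used,
            }
        )
    return pd.DataFrame(rows)


def brute_force_mean_differences(seqs) -> float:
    """Independent O(n^2 L) oracle: average Hamming distance over explicit pairs."""
    seqs = list(seqs)
    diffs = [
        sum(a != b for a, b in zip(s1, s2))
        for s1, s2 in itertools.combinations(seqs, 2)
    ]
    return sum(diffs) / len(diffs)
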