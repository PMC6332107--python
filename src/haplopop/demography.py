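"""Neutrality tests and mismatch-distribution demography.

Tajima's D contrasts the mean number of pairwise differences with the scaled
count of segregating sites; Fu's Fs is built from the Ewens sampling
probability of observing at least the sampled number of haplotypes given
theta estimated by the mean pairwise differences. Both get p-values from
neutral constant-size coalescent simulation conditioned on (n, theta-hat).

The mismatch analysis fits the sudden-expansion model: a population at
scaled size theta0 grows instantaneously to theta1 at time tau (in
mutational units, 2ut); the expected spectrum follows the transient
pairwise-difference distribution

    F_i = F_i(theta1) + exp(-tau (theta1+1)/theta1)
          * sum_{j<=i} (F_j(theta0) - F_j(theta1)) tau^(i-j)/(i-j)!

with F_j(theta) = theta^j / (1+theta)^(j+1) the equilibrium geometric law.
Goodness of fit uses the SSD statistic and Harpending's raggedness index with
parametric-bootstrap p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

from .alignment import Alignment
from .diversity import mean_pairwise_differences, pairwise_difference_matrix


# ---------------------------------------------------------------------------
# internal neutral/expansion coalescent (infinite sites)
# ---------------------------------------------------------------------------

def _simulate_branches(
    n: int, rng: np.random.Generator, expansion: tuple[float, float] | None = None
) -> list[tuple[int, float]]:
    """Kingman genealogy; returns (leaf bitmask, branch length) per branch.

    ``expansion=(t_e, nu0)``: relative population size is 1 on [0, t_e) and
    nu0 further in the past (instantaneous change looking backwards).
    """
    active = [(1 << i, 0.0) for i in range(n)]  # (mask, birth time)
    t = 0.0
    nu = 1.0
    boundary = expansion[0] if expansion else math.inf
    branches: list[tuple[int, float]] = []
    while len(active) > 1:
        k = len(active)
        rate = k * (k - 1) / 2.0 / nu
        w = rng.exponential(1.0 / rate)
        if t + w > boundary:
            t = boundary
            nu = expansion[1]
            boundary = math.inf
            continue
        t += w
        i, j = rng.choice(k, size=2, replace=False)
        (mi, bi), (mj, bj) = active[i], active[j]
        branches.append((mi, t - bi))
        branches.append((mj, t - bj))
        active = [active[x] for x in range(k) if x not in (i, j)]
        active.append((mi | mj, t))
    return branches


def _replicate_stats(
    n: int,
    theta: float,
    rng: np.random.Generator,
    expansion: tuple[float, float] | None = None,
    want_spectrum: bool = False,
):
    """One neutral replicate: (S, M, K[, pairwise difference counts])."""
    branches = _simulate_branches(n, rng, expansion)
    lens = np.array([b[1] for b in branches])
    muts = rng.poisson(theta / 2.0 * lens)
    S = int(muts.sum())
    counts = np.array([bin(b[0]).count("1") for b in branches])
    pairs = n * (n - 1) / 2.0
    M = float((muts * counts * (n - counts)).sum() / pairs)
    mutated = [i for i in range(len(branches)) if muts[i] > 0]
    sigs: dict[int, list[int]] = {i: [] for i in range(n)}
    for bi in mutated:
        mask = branches[bi][0]
        for leaf in range(n):
            if mask >> leaf & 1:
                sigs[leaf].append(bi)
    K = len({tuple(v) for v in sigs.values()})
    if not want_spectrum:
        return S, M, K
    if mutated:
        A = np.array(
            [[branches[bi][0] >> leaf & 1 for leaf in range(n)] for bi in mutated],
            dtype=float,
        )
        w = muts[mutated].astype(float)
        s1 = (A * w[:, None]).sum(axis=0)
        cross = A.T @ (A * w[:, None])
        D = s1[:, None] + s1[None, :] - 2 * cross
    else:
        D = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    return S, M, K, np.rint(D[iu]).astype(int)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict[str, float]:
    """Tajima's (1989) a1, a2, b1, b2, c1, c2, e1, e2 for sample size n."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def _tajimas_d_from(S: int, M: float, n: int) -> float:
    c = tajima_constants(n)
    denom = math.sqrt(c["e1"] * S + c["e2"] * S * (S - 1))
    return (M - S / c["a1"]) / denom


def tajimas_d(
    aln: Alignment,
    replicates: int = 10000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Tajima's D with a simulation p-value.

    The p-value is the two-tailed fraction of neutral constant-size coalescent
    replicates (n, theta = observed M) whose |D| meets or exceeds |observed|.
    Raises if the alignment has no segregating site (statistic undefined).
    """
    from .diversity import pairwise_difference_stats

    stats = pairwise_difference_stats(aln)
    if stats.S == 0:
        raise ValueError("Tajima's D undefined: no segregating sites")
    d_obs = _tajimas_d_from(stats.S, stats.M, aln.n)
    if replicates < 1:
        return d_obs, float("nan")
    rng = np.random.default_rng(seed)
    hits = total = 0
    for _ in range(replicates):
        S, M, _ = _replicate_stats(aln.n, stats.M, rng)
        if S == 0:
            continue
        total += 1
        if abs(_tajimas_d_from(S, M, aln.n)) >= abs(d_obs) - 1e-12:
            hits += 1
    p = hits / total if total else float("nan")
    return d_obs, p


# ---------------------------------------------------------------------------
# Fu's Fs via the Ewens sampling formula
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _log_stirling_row(n: int) -> np.ndarray:
    """log of unsigned Stirling numbers of the first kind c(n, k), k = 0..n."""
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # c(0,0) = 1
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        new[1 : m + 1] = np.logaddexp(
            row[0:m],  # c(m-1, k-1)
            math.log(m - 1) + row[1 : m + 1] if m > 1 else -np.inf,
        )
        row = new
    return row


def ewens_k_distribution(n: int, theta: float) -> np.ndarray:
    """P(K = k) for k = 0..n under the Ewens sampling formula.

    P(K=k) = |s(n,k)| theta^k / theta^(n) (rising factorial), computed in
    log space with an exact Stirling-number recurrence.
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    lrow = _log_stirling_row(n)
    lrising = sum(math.log(theta + i) for i in range(n))
    k = np.arange(n + 1)
    logp = lrow + k * math.log(theta) - lrising
    return np.exp(logp)


def fus_fs(
    aln: Alignment,
    replicates: int = 10000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Fu's Fs with a simulation p-value.

    S' = P(K >= k_obs | theta = M, n) under the Ewens sampling formula and
    Fs = ln(S'/(1-S')). Strongly negative values indicate an excess of
    haplotypes relative to the pairwise diversity, as after an expansion.
    The p-value is the fraction of neutral replicates with Fs <= observed.
    """
    from .alignment import PopulationMap, collapse_haplotypes

    M = mean_pairwise_differences(aln)
    if M == 0:
        raise ValueError("Fu's Fs undefined: no pairwise differences (M = 0)")
    pm = PopulationMap({i: "all" for i in aln.ids})
    k_obs = collapse_haplotypes(aln, pm).n_haplotypes
    fs_obs = _fs_statistic(aln.n, M, k_obs)
    if replicates < 1:
        return fs_obs, float("nan")
    rng = np.random.default_rng(seed)
    hits = total = 0
    for _ in range(replicates):
        _, M_r, K_r = _replicate_stats(aln.n, M, rng)
        if M_r == 0:
            continue
        total += 1
        if _fs_statistic(aln.n, M_r, K_r) <= fs_obs + 1e-12:
            hits += 1
    p = hits / total if total else float("nan")
    return fs_obs, p


def _fs_statistic(n: int, theta: float, k_obs: int) -> float:
    lrow = _log_stirling_row(n)
    lrising = sum(math.log(theta + i) for i in range(n))
    k = np.arange(n + 1)
    logp = lrow + k * math.log(theta) - lrising
    log_sp = logsumexp(logp[k_obs:])
    # clamp to keep the logit finite at numerical extremes
    log_sp = min(log_sp, -1e-12)
    sp = math.exp(log_sp)
    eps = 1e-300
    sp = min(max(sp, eps), 1 - 1e-15)
    return math.log(sp / (1.0 - sp))


# ---------------------------------------------------------------------------
# mismatch distributions and the sudden-expansion model
# ---------------------------------------------------------------------------

@dataclass
class MismatchFit:
    observed: np.ndarray
    tau: float
    theta0: float
    theta1: float
    expected: np.ndarray
    ssd: float
    converged: bool = True
    raggedness: float | None = None
    p_ssd: float | None = None
    p_raggedness: float | None = None


def mismatch_observed(aln: Alignment) -> np.ndarray:
    """Relative frequency of each pairwise difference count, classes 0..max."""
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    d = pairwise_difference_matrix(aln)
    iu = np.triu_indices(aln.n, k=1)
    vals = d[iu]
    spectrum = np.bincount(vals.astype(int)) / len(vals)
    return spectrum


def count_modes(spectrum, prominence: float = 0.02) -> int:
    """Number of major modes of a mismatch spectrum.

    A mode is a peak with the given prominence (mass units) after padding the
    support with zeros, so small sampling jitter does not register; sudden
    expansions yield one mode, stable structured populations several.
    """
    from scipy.signal import find_peaks

    padded = np.concatenate([[0.0], np.asarray(spectrum, dtype=float), [0.0]])
    peaks, _ = find_peaks(padded, prominence=prominence)
    return len(peaks)


def _equilibrium(theta: float, i: np.ndarray) -> np.ndarray:
    if theta == 0:
        return (i == 0).astype(float)
    # log space: theta^i / (1+theta)^(i+1) overflows for large theta * i
    return np.exp(i * math.log(theta) - (i + 1) * math.log1p(theta))


def expected_sudden_expansion(
    tau: float, theta0: float, theta1: float, d_max: int
) -> np.ndarray:
    """Expected mismatch probabilities under instantaneous growth theta0->theta1.

    Returns classes 0..d_max; the final class absorbs the tail mass so the
    vector sums to one.
    """
    if min(tau, theta0, theta1) < 0:
        raise ValueError("parameters must be >= 0")
    # evaluate far enough beyond d_max that the aggregated tail is exact
    span = int(max(2 * d_max + 20, tau + 10 * math.sqrt(tau + 1), 50))
    i = np.arange(span + 1)
    f1 = _equilibrium(theta1, i)
    if tau == 0:
        full = _equilibrium(theta0, i)
    else:
        f0 = _equilibrium(theta0, i)
        diff = f0 - f1
        if theta1 == 0:
            decay = 0.0
        else:
            decay = math.exp(-tau * (theta1 + 1.0) / theta1)
        # convolution of (f0 - f1) with the Poisson(tau) increment law
        log_tau = math.log(tau)
        pois = np.exp(i * log_tau - gammaln(i + 1))
        conv = np.convolve(diff, pois)[: span + 1]
        full = f1 + decay * conv
    full = np.clip(full, 0.0, None)
    out = np.empty(d_max + 1)
    out[:d_max] = full[:d_max]
    out[d_max] = max(1.0 - full[:d_max].sum(), 0.0)
    return out


def _ssd(observed: np.ndarray, params: tuple[float, float, float]) -> float:
    tau, th0, th1 = params
    exp = expected_sudden_expansion(tau, th0, th1, len(observed) - 1)
    return float(((observed - exp) ** 2).sum())


def fit_sudden_expansion(
    observed: np.ndarray,
    tau_max: float | None = None,
    theta_max: float | None = None,
    coarse: int = 6,
) -> MismatchFit:
    """Least-squares fit of (tau, theta0, theta1) to an observed spectrum.

    A coarse grid over plausible parameter values seeds a Nelder-Mead
    refinement in square-root space (which enforces non-negativity); the
    procedure is deterministic.
    """
    observed = np.asarray(observed, dtype=float)
    if len(observed) < 2:
        raise ValueError("spectrum too short to fit")
    d_max = len(observed) - 1
    mean_d = float((np.arange(d_max + 1) * observed).sum())
    tau_max = tau_max if tau_max is not None else max(2.0 * d_max, 5.0)
    theta_max = theta_max if theta_max is not None else max(20.0 * (mean_d + 1), 1000.0)

    taus = np.linspace(0.0, tau_max, max(coarse, 16) + 1)
    th0s = [0.0, 0.5, 1.0, 2.0, 5.0, mean_d / 2 + 0.5]
    th1s = [1.0, 5.0, 20.0, 50.0, 200.0, mean_d + 1, theta_max]
    grid = sorted(
        (( _ssd(observed, (t, a, b)), (t, a, b))
         for t in taus for a in th0s for b in th1s),
        key=lambda v: v[0],
    )

    def objective(x):
        return _ssd(observed, tuple(x * x))

    best_params, best_ssd = grid[0][1], grid[0][0]
    converged = False
    for _, start in grid[:3]:  # polish the best few grid points
        res = minimize(
            objective, np.sqrt(np.array(start)), method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-16,
                     "maxiter": 6000, "maxfev": 6000},
        )
        if res.fun < best_ssd:
            best_ssd = float(res.fun)
            best_params = tuple(float(v * v) for v in res.x)
            converged = bool(res.success)
    params, ssd = best_params, best_ssd
    expected = expected_sudden_expansion(*params, d_max)
    return MismatchFit(
        observed=observed,
        tau=params[0],
        theta0=params[1],
        theta1=params[2],
        expected=expected,
        ssd=ssd,
        converged=converged,
    )


def raggedness_index(spectrum: np.ndarray) -> float:
    """Harpending's raggedness r = sum (x_i - x_{i-1})^2 with x_{d+1} := 0."""
    x = np.append(np.asarray(spectrum, dtype=float), 0.0)
    return float((np.diff(x) ** 2).sum())


def goodness_of_fit(
    fit: MismatchFit,
    n: int,
    bootstrap_reps: int = 1000,
    seed: int | None = None,
    refit: bool = True,
) -> MismatchFit:
    """Parametric-bootstrap p-values for SSD and raggedness.

    Coalescent samples of size n are simulated under the fitted expansion,
    each replicate is refit, and p is the fraction of replicates whose
    statistic meets or exceeds the observed one.
    """
    rng = np.random.default_rng(seed)
    r_obs = raggedness_index(fit.observed)
    tau, th0, th1 = fit.tau, fit.theta0, fit.theta1
    if th1 <= 0:
        raise ValueError("fitted theta1 must be positive for the bootstrap")
    t_e = tau / th1
    nu0 = th0 / th1
    hits_ssd = hits_r = 0
    for _ in range(bootstrap_reps):
        _, _, _, diffs = _replicate_stats(
            n, th1, rng, expansion=(t_e, nu0), want_spectrum=True
        )
        spec = np.bincount(diffs, minlength=1).astype(float)
        spec /= spec.sum()
        if refit:
            rep_fit = fit_sudden_expansion(spec)
            rep_ssd = rep_fit.ssd
        else:
            rep_ssd = _ssd_on_common_support(spec, (tau, th0, th1))
        if rep_ssd >= fit.ssd - 1e-15:
            hits_ssd += 1
        if raggedness_index(spec) >= r_obs - 1e-15:
            hits_r += 1
    fit.raggedness = r_obs
    fit.p_ssd = hits_ssd / bootstrap_reps
    fit.p_raggedness = hits_r / bootstrap_reps
    return fit


def _ssd_on_common_support(spec: np.ndarray, params) -> float:
    exp = expected_sudden_expansion(*params, len(spec) - 1)
    return float(((spec - exp) ** 2).sum())


def neutrality_table(
    aln: Alignment,
    pm,
    replicates: int = 10000,
    seed=None,
    mismatch_boot: int | None = None,
):
    """Per-population and pooled D, Fs, tau, SSD and raggedness report.

    ``mismatch_boot`` caps the parametric-bootstrap replicates for the SSD /
    raggedness p-values (each one involves a full refit); it defaults to
    min(replicates, 200).
    """
    import pandas as pd

    from .alignment import PopulationMap

    ss = np.random.SeedSequence(seed)
    rows = []
    groups = list(pm.populations) + ["Total"]
    seeds = ss.spawn(2 * len(groups))
    for gi, pop in enumerate(groups):
        sub = aln if pop == "Total" else aln.subset(pm.members(pop))
        row: dict = {"population": pop, "n": sub.n}
        try:
            d, p_d = tajimas_d(sub, replicates, seeds[2 * gi].generate_state(1)[0])
            row.update(D=d, p_D=p_d)
        except ValueError:
            row.update(D=float("nan"), p_D=float("nan"))
        try:
            fs, p_fs = fus_fs(sub, replicates, seeds[2 * gi].generate_state(2)[1])
            row.update(Fs=fs, p_Fs=p_fs)
        except ValueError:
            row.update(Fs=float("nan"), p_Fs=float("nan"))
        spec = mismatch_observed(sub)
        fit = fit_sudden_expansion(spec)
        boot = mismatch_boot if mismatch_boot is not None else min(replicates, 200)
        fit = goodness_of_fit(
            fit, sub.n, bootstrap_reps=boot,
            seed=seeds[2 * gi + 1].generate_state(1)[0],
        )
        row.update(
            tau=fit.tau, theta0=fit.theta0, theta1=fit.theta1,
            SSD=fit.ssd, p_SSD=fit.p_ssd,
            raggedness=fit.raggedness, p_raggedness=fit.p_raggedness,
        )
        rows.append(row)
    return pd.DataFrame(rows)
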