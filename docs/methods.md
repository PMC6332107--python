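# Methods

This note documents the statistical procedures implemented in haplopop, the
choices made where conventions differ between programs, and what the
synthetic-data generator does and does not emulate.

## Input model and site filtering

All statistics operate on one aligned multi-FASTA of equal-length
nucleotide sequences over `{A,C,G,T,N,-}` plus an id→population map.
A single global *complete deletion* pass removes every column containing a
gap or `N` in any sequence before anything is computed; pairwise deletion is
deliberately not offered, so every statistic sees the same rectangular
matrix and results are reproducible across modules. Ambiguity codes other
than `N` are rejected at read time. Haplotype identity is exact string
equality on the filtered matrix; haplotype order follows first occurrence.

A variable site is *parsimony-informative* iff at least two distinct bases
are each carried by at least two sequences, otherwise it is a singleton
site. Transitions and transversions are counted over unordered pairs of
distinct bases observed per site (not per sequence pair), and the ratio is
reported as Tv/Ts.

## Diversity indices

- Haplotype diversity: Nei's unbiased estimator
  `Hd = n/(n−1)·(1 − Σ p_i²)` with Nei's (1987) sampling variance
  `V = 2/(n(n−1))·[2(n−2)(Σp³ − (Σp²)²) + Σp² − (Σp²)²]`.
- Mean pairwise differences M: average Hamming distance over all
  n(n−1)/2 pairs. Nucleotide diversity π = M/L on the filtered length, so
  π·L = M is checkable in every report.
- SDs of π (and hence M = π·L) use Tajima's (1983) *total* variance under
  no recombination,
  `V(π) = (n+1)/(3(n−1)L)·π + 2(n²+n+3)/(9n(n−1))·π²`,
  which includes the evolutionary (stochastic) component; this is why the
  reported SDs scale with the statistic (SD ≈ π/2) instead of shrinking
  with sample size. Reports state L so the identity is auditable.

## Distances, trees, networks

K2P distances use the closed form `d = −½ln(1−2P−Q) − ¼ln(1−2Q)` with P/Q
the transition/transversion proportions; a non-positive log argument raises
a saturation error naming the pair. Neighbor joining is Saitou–Nei
agglomeration with the Studier–Keppler Q-criterion; ties in Q are broken by
the lexicographically smallest leaf-label pair so runs are reproducible, and
negative branch lengths are truncated to zero with a flag. Distances and
trees are computed between haplotypes by default (the usual presentation for
control-region data); bootstrap resamples filtered columns with replacement
and maps the percentage of replicates containing each internal bipartition
onto the point-estimate tree (no consensus tree is built). Replicates with
an undefined K2P distance are dropped and counted.

Median-joining networks iterate: build the ε-relaxed minimum spanning
network (edge kept iff its length is within ε of the minimax path weight
between its endpoints; ε defaults to 0, i.e. the union of all MSTs), propose
per-site-majority quasi-medians for triplets adjacent in that network
(three-way ties expand to all combinations, capped at a configurable 1000
per triplet), admit greedily those candidates that shorten the minimum
spanning tree, and finally prune median vectors whose removal leaves the
spanning length unchanged. Edge weights are substitution counts over the
segregating columns. Note that once medians are admitted, direct
observed–observed MSN edges may be replaced by shorter paths through
medians; connectivity is always preserved and total length never exceeds
the observed-only MST length.

## AMOVA, fixation indices, Da, Mantel

One-level AMOVA uses raw pairwise nucleotide difference counts as squared
inter-individual distances (the haplotypic convention; squared K2P is
available as an option):

```
SS_total  = (1/N) Σ_{i<j} δ²_ij           SS_within = Σ_p (1/n_p) Σ_{i<j∈p} δ²_ij
Vb = SS_within/(N−k)                      n' = (N − Σn_p²/N)/(k−1)
Va = (SS_among/(k−1) − Vb)/n'             Φ_ST = Va/(Va+Vb)
```

Permutation p-values reshuffle individuals across populations, count the
observed statistic in numerator and denominator, and are seed-reproducible.
Negative variance components are reported as computed, never truncated.

Pairwise statistics are emitted in two modes: *frequency* (Weir–Cockerham θ
treating each haplotype as an allele at one haploid locus, summing the
among/within components over alleles) and *distance* (two-population AMOVA
Φ_ST, which exactly equals the full AMOVA restricted to the pair). Because
the θ estimator subtracts expected sampling noise, two samples with
identical haplotype frequency vectors yield a (slightly) negative θ rather
than exactly zero; this is a property of the unbiased estimator and is left
visible. The corrected divergence `Da = PiXY − (PiX+PiY)/2` uses plain
cross- and within-population means of difference counts; between two copies
of the same polymorphic sample it equals −PiX/n (the cross mean includes
zero-distance twin pairs), vanishing with sample size.

The Mantel test correlates the condensed upper triangles, permutes
rows/columns of the second matrix jointly, and reports a one-sided
(greater) p with the observed value included; an exact mode enumerates all
k! permutations for small k. Geographic distances are consumed as a
user-supplied matrix — a great-circle helper is provided, but path-like
distances (e.g. along a coastline) are the user's responsibility.
Bonferroni correction flags p ≤ α/m over the m pairwise comparisons.

## Model-based clustering

Each cluster is a product of independent per-site base-frequency models
with a symmetric Dirichlet prior (α = 0.25 per base); a partition's score is
the sum over clusters and sites of the Dirichlet-multinomial log marginal
likelihood of the cluster's base counts. The search is deliberately simple
and deterministic given a seed: for each k up to k_max (default 10), five
(default) random restarts of a greedy loop that applies the best
single-individual reassignment until no move improves the score. The
best-scoring partition across all k is returned together with every
replicate's score; model selection is by maximum marginal likelihood, not
averaging. Membership probabilities are leave-self-out predictive
probabilities of each individual under each fitted cluster profile,
renormalized per individual.

## Neutrality tests and mismatch analysis

θ̂ for both tests is M, matching the definitions of the cited statistics.

- Tajima's D = `(M − S/a1)/√(e1·S + e2·S(S−1))` with the standard a1, a2,
  b1, b2, c1, c2, e1, e2 coefficients (validated against exact rational
  arithmetic in the tests). S = 0 raises rather than returning 0.
- Fu's Fs: `S' = P(K ≥ k_obs | θ = M, n)` under the Ewens sampling formula,
  `P(K=k) = |s(n,k)|·θᵏ/(θ)ₙ`, with unsigned Stirling numbers of the first
  kind computed by a log-space recurrence (exact rational oracle in tests
  for small n); `Fs = ln(S'/(1−S'))`, clamped at numerical extremes.
- p-values come from a pure-numpy infinite-sites neutral coalescent
  conditioned on (n, θ̂): two-tailed on |D| for Tajima, lower-tailed for Fs.
  The default is 10,000 replicates; calibration tests in the suite use
  1000/3000 and the pipeline accepts any count.

The observed mismatch distribution is the relative frequency of pairwise
difference counts. The sudden-expansion model (θ0 → θ1 at time τ in units
of 2ut) has expected spectrum

```
F_i = F_i(θ1) + exp(−τ(θ1+1)/θ1) · Σ_{j≤i} (F_j(θ0) − F_j(θ1)) τ^{i−j}/(i−j)!
F_j(θ) = θʲ/(1+θ)^{j+1}
```

evaluated in log space; the final class absorbs the tail so every spectrum
sums to one. Fitting minimizes the plain sum of squared deviations over
(τ, θ0, θ1) by a coarse grid (17 τ values × small θ grids) followed by
Nelder–Mead refinement in square-root space from the three best grid
points; the procedure is deterministic and recovers exact model spectra to
SSD < 1e−20. At a stationary spectrum the model is non-identifiable in τ
(the transient term vanishes for any large τ), which is reported as
computed — SSD is flat, θ1 is still recovered. Weighted (generalized)
least squares is intentionally not used; plain SSD keeps the objective
transparent.

Goodness of fit: parametric bootstrap — coalescent samples of size n under
the fitted expansion (time-rescaled Kingman genealogy with relative size
θ0/θ1 beyond τ/θ1), each replicate refit, p = fraction of replicates with
SSD (or raggedness) at or above the observed value. Harpending's raggedness
uses the convention `r = Σ_{i=1}^{d+1}(x_i − x_{i−1})²` with `x_{d+1} := 0`
(classes start at 0); sources differ on the boundary term, so the
convention is fixed here and used consistently. A helper classifies spectra
as unimodal/multimodal by counting peaks with prominence ≥ 0.02 after
zero-padding, which ignores sampling jitter while separating expansion-like
from structured spectra.

## Substitution saturation

ISS = mean per-site Shannon entropy of the alignment divided by the
Monte-Carlo mean entropy of fully saturated alignments (every site i.i.d.
from the global base frequencies, same n and L). ISS_c is the 5% quantile
of the simulated saturated ISS distribution: observed values below it are
essentially never produced by saturated data, so `ISS < ISS_c` flags the
alignment as retaining signal, with a one-sided Monte-Carlo p. This is a
re-derivation of the entropy-based index from its definition, calibrated
internally under a star topology; equivalence with any particular program's
tabulated critical values is not claimed. Because the full-saturation mean
entropy carries the usual finite-sample bias (≈ (K−1)/(2n ln 2) per site),
ISS is only asymptotically invariant to duplicating every sequence.

## Synthetic data

The generator wraps msprime: haploid samples in unit-size demes, so time is
in coalescent units of N generations and θ (per locus) is twice the
per-locus mutation rate per time unit; the expected pairwise difference
count within a panmictic deme equals θ. Topologies supported: island-model
migration (total emigration rate split evenly), a two-region divergence
(demes split from regional ancestors, regions merge at a deeper time, with
within-region migration), and an instantaneous size change at τ/θ1 for
expansion studies. Mutations follow HKY with configurable κ and base
frequencies; the event rate is rescaled by the model's silent-event
fraction so the realized substitution rate matches θ/(2L) per site. The
default base frequencies (0.443, 0.161, 0.083, 0.313) and κ = 17.9 are
chosen so the realized Tv/Ts ratio is ≈ 0.16, typical of crustacean
control-region data. Every dataset carries a JSON manifest (config, seed,
FASTA hash) and regenerates bit-identically from its seed.

The five-deme preset (sizes 15/15/22/21/24, 710 bp, three-deme and two-deme
regions, within-region migration 10, splits at 1.0 and 3.5, θ = 100) was
calibrated once so that the median AMOVA Φ_ST across seeds is ≈ 0.48
(within [0.35, 0.60]) and ≈ 90% of sampled sequences are unique haplotypes.
Two caveats about realism: (i) within-population diversity under this
equilibrium preset is several times higher than typical real
control-region data — matching both near-complete haplotype uniqueness at
n ≈ 97 and low within-population M would require recent-expansion
demographies, which here inflate Φ_ST well above 0.5; (ii) the simulator
has no rate heterogeneity across sites, no indels and no selection, so
passing recovery tests demonstrates correctness of the estimators under the
generating model, not robustness to those real-data features. Single-seed
Φ_ST realizations scatter widely (≈ 0.28–0.57); conclusions about the
preset's structure level should always use several seeds.

## Pipeline and problem sizes

The pipeline derives one seed per stochastic stage from the run seed
(SeedSequence spawning), so reruns are byte-identical. Defaults follow
standard practice for this analysis type: 10,000 permutations for
AMOVA/F_ST/Mantel, 1000 tree bootstrap replicates, 10,000 neutrality-test
replicates, k_max = 10 with 5 clustering restarts. The mismatch
parametric bootstrap defaults to 200 replicates because each one involves
a full refit; it is configurable (`mismatch_boot`). The test suite and the
calibration studies it contains use smaller sizes chosen for quick
iteration (e.g. 99–999 permutations, 1000-replicate neutral calibration at
n = 30, θ = 5; 500 expansion recoveries at n = 50; 9 preset realizations
for the Φ_ST median), which are ample for the tolerances asserted.

## Known limitations

- Single non-recombining locus throughout; no recombination anywhere.
- Complete deletion is the only missing-data policy.
- The clustering search is greedy with restarts; it can in principle miss
  the global optimum on weakly separated data (scores of all replicates are
  reported so this is visible).
- Mismatch fitting uses unweighted SSD; programs using generalized least
  squares will give slightly different (τ, θ) point estimates.
- ISS_c is calibrated under a symmetric star topology only.
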