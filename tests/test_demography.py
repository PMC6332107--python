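import math
from fractions import Fraction

import numpy as np
import pytest

from haplopop.alignment import Alignment
from haplopop.demography import (
    _fs_statistic,
    _replicate_stats,
    count_modes,
    ewens_k_distribution,
    expected_sudden_expansion,
    fit_sudden_expansion,
    fus_fs,
    goodness_of_fit,
    mismatch_observed,
    raggedness_index,
    tajima_constants,
    tajimas_d,
)


def exact_ewens_tail(n, theta: Fraction, k_obs):
    """Exact rational P(K >= k_obs) via Stirling numbers of the first kind."""
    # c(n, k) by the integer recurrence
    c = [[0] * (n + 1) for _ in range(n + 1)]
    c[0][0] = 1
    for m in range(1, n + 1):
        for k in range(1, m + 1):
            c[m][k] = c[m - 1][k - 1] + (m - 1) * c[m - 1][k]
    rising = Fraction(1)
    for i in range(n):
        rising *= theta + i
    probs = [Fraction(c[n][k]) * theta**k / rising for k in range(n + 1)]
    assert sum(probs) == 1
    return sum(probs[k_obs:])


def exact_tajima_d(seqs):
    """Independent rational-arithmetic evaluation of every Tajima coefficient."""
    n = len(seqs)
    L = len(seqs[0])
    S = sum(1 for j in range(L) if len({s[j] for s in seqs}) > 1)
    diffs = [
        sum(a != b for a, b in zip(seqs[i], seqs[j]))
        for i in range(n)
        for j in range(i + 1, n)
    ]
    M = Fraction(sum(diffs), len(diffs))
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float(M - S / a1) / math.sqrt(float(var))


class TestTajimasD:
    def test_no_segregating_sites_raises(self):
        aln = Alignment(("a", "b", "c", "d"), ("ACGT",) * 4)
        with pytest.raises(ValueError):
            tajimas_d(aln, replicates=0)

    def test_four_sequence_toy_against_rational_oracle(self):
        seqs = ("AAAAA", "AAAAT", "AAATT", "AATTT")
        aln = Alignment(("s1", "s2", "s3", "s4"), seqs)
        d, _ = tajimas_d(aln, replicates=0)
        assert d == pytest.approx(exact_tajima_d(seqs), rel=1e-12)

    def test_coefficients_match_rational_arithmetic(self):
        for n in range(4, 31):
            c = tajima_constants(n)
            a1 = sum(Fraction(1, i) for i in range(1, n))
            a2 = sum(Fraction(1, i * i) for i in range(1, n))
            b1 = Fraction(n + 1, 3 * (n - 1))
            b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
            c1 = b1 - 1 / a1
            c2 = b2 - Fraction(n + 2) / (a1 * n) + a2 / a1**2
            assert c["e1"] == pytest.approx(float(c1 / a1), rel=1e-12)
            assert c["e2"] == pytest.approx(float(c2 / (a1**2 + a2)), rel=1e-12)

    def test_neutral_simulations_slightly_negative_mean(self):
        rng = np.random.default_rng(17)
        ds = []
        for _ in range(1000):
            S, M, _ = _replicate_stats(30, 5.0, rng)
            if S > 0:
                c = tajima_constants(30)
                ds.append(
                    (M - S / c["a1"]) / math.sqrt(c["e1"] * S + c["e2"] * S * (S - 1))
                )
        assert -0.2 <= np.mean(ds) <= 0.1

    def test_p_value_seed_reproducible(self, toy_triplet):
        aln = Alignment(
            ("a", "b", "c", "d"),
            ("AAAAAAAACC", "AAAATTAACC", "AAAATTAAGG", "TTAATTAAGG"),
        )
        d1, p1 = tajimas_d(aln, replicates=200, seed=5)
        d2, p2 = tajimas_d(aln, replicates=200, seed=5)
        assert d1 == d2 and p1 == p2


class TestFusFs:
    def test_two_sequences_one_difference_is_zero(self):
        aln = Alignment(("a", "b"), ("AAAA", "AAAT"))
        fs, _ = fus_fs(aln, replicates=0)
        assert fs == pytest.approx(0.0, abs=1e-12)

    def test_matches_exact_rational_oracle(self):
        # n=5, 4 haplotypes, M rational
        seqs = ("AAAAA", "AAAAT", "AAATT", "AAATT", "TAATT")
        aln = Alignment(tuple(f"s{i}" for i in range(5)), seqs)
        fs, _ = fus_fs(aln, replicates=0)
        diffs = [
            sum(a != b for a, b in zip(seqs[i], seqs[j]))
            for i in range(5)
            for j in range(i + 1, 5)
        ]
        M = Fraction(sum(diffs), len(diffs))
        sp = exact_ewens_tail(5, M, 4)
        expected = math.log(float(sp / (1 - sp)))
        assert fs == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("n,theta", [(8, Fraction(3, 2)), (6, Fraction(7))])
    def test_statistic_against_oracle_parametrized(self, n, theta):
        for k_obs in range(2, n + 1):
            sp = exact_ewens_tail(n, theta, k_obs)
            expected = math.log(float(sp / (1 - sp)))
            assert _fs_statistic(n, float(theta), k_obs) == pytest.approx(
                expected, rel=1e-9
            )

    def test_ewens_distribution_sums_to_one(self):
        for n, theta in [(10, 0.3), (50, 5.0), (100, 27.0)]:
            assert ewens_k_distribution(n, theta).sum() == pytest.approx(
                1.0, abs=1e-10
            )

    def test_m_zero_raises(self):
        aln = Alignment(("a", "b"), ("AAAA", "AAAA"))
        with pytest.raises(ValueError):
            fus_fs(aln, replicates=0)

    def test_expansion_simulations_give_negative_mean_fs(self):
        rng = np.random.default_rng(23)
        vals = []
        for _ in range(150):
            S, M, K = _replicate_stats(25, 10.0, rng, expansion=(0.05, 0.01))
            if M > 0:
                vals.append(_fs_statistic(25, M, K))
        assert np.mean(vals) < 0


class TestMismatch:
    def test_identical_sequences_point_mass(self):
        aln = Alignment(("a", "b", "c"), ("ACGT",) * 3)
        spec = mismatch_observed(aln)
        assert spec[0] == 1.0 and len(spec) == 1

    def test_triplet_spectrum(self, toy_triplet):
        spec = mismatch_observed(toy_triplet)
        assert spec[2] == pytest.approx(2 / 3)
        assert spec[4] == pytest.approx(1 / 3)

    def test_equilibrium_closed_form_theta_one(self):
        spec = expected_sudden_expansion(0.0, 1.0, 1.0, 25)
        expected = np.array([2.0 ** -(i + 1) for i in range(25)])
        assert np.abs(spec[:25] - expected).max() < 1e-12

    @pytest.mark.parametrize(
        "tau,th0,th1", [(0, 2, 2), (5, 1, 50), (22, 0.5, 400), (10, 0, 100)]
    )
    def test_spectrum_is_distribution(self, tau, th0, th1):
        spec = expected_sudden_expansion(tau, th0, th1, 60)
        assert spec.min() >= 0
        assert spec.sum() == pytest.approx(1.0, abs=1e-9)

    def test_peak_near_tau(self):
        spec = expected_sudden_expansion(10.0, 0.01, 100.0, 40)
        assert abs(int(np.argmax(spec)) - 10) <= 1

    def test_fit_self_consistency(self):
        obs = expected_sudden_expansion(5.0, 1.0, 50.0, 40)
        fit = fit_sudden_expansion(obs)
        assert fit.ssd < 1e-8
        assert fit.tau == pytest.approx(5.0, abs=0.05)

    def test_equilibrium_data_make_tau_unidentifiable(self):
        obs = expected_sudden_expansion(0.0, 8.0, 8.0, 50)
        fit = fit_sudden_expansion(obs)
        assert fit.ssd < 1e-10
        # the SSD surface is flat in tau: tau = 0 with theta0 = theta1 fits
        # exactly as well as whatever the optimizer landed on
        from haplopop.demography import _ssd

        assert _ssd(obs, (0.0, 8.0, 8.0)) < 1e-20
        assert fit.theta1 == pytest.approx(8.0, rel=0.05)

    def test_raggedness_hand_sum(self):
        assert raggedness_index([0.25, 0.5, 0.25]) == pytest.approx(0.1875)

    def test_raggedness_smooth_below_spiky(self):
        smooth = np.array([2.0 ** -(i + 1) for i in range(10)])
        smooth /= smooth.sum()
        spiky = np.zeros(10)
        spiky[2] = spiky[7] = 0.5
        assert raggedness_index(smooth) < raggedness_index(spiky)

    def test_goodness_of_fit_p_values_in_range(self):
        rng = np.random.default_rng(3)
        _, _, _, d = _replicate_stats(20, 30.0, rng, expansion=(0.3, 0.01),
                                      want_spectrum=True)
        spec = np.bincount(d).astype(float)
        spec /= spec.sum()
        fit = fit_sudden_expansion(spec)
        fit = goodness_of_fit(fit, n=20, bootstrap_reps=60, seed=4)
        assert 0.0 <= fit.p_ssd <= 1.0
        assert 0.0 <= fit.p_raggedness <= 1.0
        assert fit.raggedness == pytest.approx(raggedness_index(spec))

    def test_expansion_spectra_mostly_unimodal(self):
        rng = np.random.default_rng(31)
        unimodal = 0
        reps = 40
        for _ in range(reps):
            _, _, _, d = _replicate_stats(
                50, 100.0, rng, expansion=(0.1, 0.01), want_spectrum=True
            )
            spec = np.bincount(d).astype(float)
            spec /= spec.sum()
            if count_modes(spec) == 1:
                unimodal += 1
        assert unimodal / reps >= 0.8
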