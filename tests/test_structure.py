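import itertools

import numpy as np
import pytest

from haplopop.alignment import Alignment, PopulationMap
from haplopop.phylo import DistanceMatrix
from haplopop.structure import (
    amova,
    amova_from_ss,
    bonferroni_adjust,
    corrected_da,
    great_circle_km,
    mantel_test,
    pairwise_fst,
    weir_cockerham_fst,
)
from .conftest import random_alignment


def _labelled(seqs_by_pop):
    ids, seqs, assign = [], [], {}
    for pop, seqs_p in seqs_by_pop.items():
        for k, s in enumerate(seqs_p):
            sid = f"{pop}{k}"
            ids.append(sid)
            seqs.append(s)
            assign[sid] = pop
    return Alignment(tuple(ids), tuple(seqs)), PopulationMap(assign)


class TestAmova:
    def test_two_fixed_pairs(self):
        # pops {h1,h1} and {h2,h2} with squared distance 1 between haplotypes
        aln, pm = _labelled({"X": ["A", "A"], "Y": ["T", "T"]})
        res = amova(aln, pm, permutations=0)
        assert res.Va == pytest.approx(0.5)
        assert res.Vb == pytest.approx(0.0)
        assert res.phi_st == pytest.approx(1.0)

    def test_self_consistency_with_printed_ss(self, rng):
        aln = random_alignment(18, 60, rng)
        assign = {sid: ("A" if i < 6 else "B" if i < 12 else "C")
                  for i, sid in enumerate(aln.ids)}
        pm = PopulationMap(assign)
        res = amova(aln, pm, permutations=0)
        redo = amova_from_ss(res.ss_among, res.ss_within, [6, 6, 6])
        assert redo.Va == pytest.approx(res.Va, rel=1e-12)
        assert redo.phi_st == pytest.approx(res.phi_st, rel=1e-12)

    def test_requires_two_populations(self, rng):
        aln = random_alignment(6, 30, rng)
        pm = PopulationMap({sid: "P" for sid in aln.ids})
        with pytest.raises(ValueError):
            amova(aln, pm, permutations=0)

    def test_all_distances_zero_flagged(self):
        aln, pm = _labelled({"X": ["AA", "AA"], "Y": ["AA", "AA"]})
        res = amova(aln, pm, permutations=0)
        assert res.undefined

    def test_permutation_p_seed_reproducible(self, rng):
        aln = random_alignment(16, 50, rng)
        pm = PopulationMap(
            {sid: ("A" if i < 8 else "B") for i, sid in enumerate(aln.ids)}
        )
        p1 = amova(aln, pm, permutations=99, seed=3).p
        p2 = amova(aln, pm, permutations=99, seed=3).p
        assert p1 == p2

    def test_permutation_calibration_under_exchangeability(self):
        # random labels on exchangeable data: nominal 5% test rejects 1-10%
        rng = np.random.default_rng(99)
        rejections = 0
        sims = 200
        for _ in range(sims):
            aln = random_alignment(20, 40, rng)
            pm = PopulationMap(
                {sid: ("A" if i < 10 else "B") for i, sid in enumerate(aln.ids)}
            )
            res = amova(aln, pm, permutations=99,
                        seed=int(rng.integers(2**31)))
            if res.p is not None and res.p <= 0.05:
                rejections += 1
        assert 0.01 <= rejections / sims <= 0.10


class TestPairwiseFst:
    def test_identical_frequency_vectors_no_differentiation(self):
        # the unbiased estimator centers sampling noise at zero, so identical
        # empirical vectors land at or below zero, never above
        aln, pm = _labelled({"X": ["AA", "TT"], "Y": ["AA", "TT"]})
        res = pairwise_fst(aln, pm, mode="frequency", permutations=0)
        assert res.fst[0, 1] <= 1e-12
        # and the differentiation is statistically invisible
        res_p = pairwise_fst(aln, pm, mode="frequency", permutations=49, seed=0)
        assert res_p.p_fst[0, 1] > 0.5

    def test_fixed_difference_is_one(self):
        assert weir_cockerham_fst([2, 0], [0, 2]) == pytest.approx(1.0)
        aln, pm = _labelled({"X": ["AA", "AA"], "Y": ["TT", "TT"]})
        res = pairwise_fst(aln, pm, mode="frequency", permutations=0)
        assert res.fst[0, 1] == pytest.approx(1.0)

    def test_distance_mode_matches_amova_pair(self, rng):
        aln = random_alignment(12, 40, rng)
        pm = PopulationMap(
            {sid: ("A" if i < 6 else "B") for i, sid in enumerate(aln.ids)}
        )
        res = pairwise_fst(aln, pm, mode="distance", permutations=0)
        am = amova(aln, pm, permutations=0)
        assert res.phist[0, 1] == pytest.approx(am.phi_st, abs=1e-12)

    def test_unknown_mode(self, rng):
        aln = random_alignment(4, 10, rng)
        pm = PopulationMap(
            {sid: ("A" if i < 2 else "B") for i, sid in enumerate(aln.ids)}
        )
        with pytest.raises(ValueError):
            pairwise_fst(aln, pm, mode="banana")


class TestCorrectedDa:
    def test_identical_populations_center_at_zero(self):
        # monomorphic copies: exactly zero
        aln, pm = _labelled({"X": ["ACGT", "ACGT"], "Y": ["ACGT", "ACGT"]})
        assert corrected_da(aln, pm).da[0, 1] == pytest.approx(0.0, abs=1e-12)
        # polymorphic copies: the cross mean includes zero-distance twin
        # pairs, giving exactly -PiX/n (vanishing with sample size)
        aln, pm = _labelled({"X": ["ACGT", "AGGT"], "Y": ["ACGT", "AGGT"]})
        res = corrected_da(aln, pm)
        assert res.da[0, 1] == pytest.approx(-1.0 / 2, abs=1e-12)

    def test_hand_worked_cross_pairs(self):
        aln, pm = _labelled({"X": ["AAAA", "AAAT"], "Y": ["TTTT", "TTTA"]})
        res = corrected_da(aln, pm)
        # PiX = PiY = 1, cross pairs: 4,3,3,4 -> PiXY = 3.5, Da = 2.5
        assert res.da[0, 1] == pytest.approx(2.5)

    def test_matches_brute_force_and_symmetry(self, rng):
        aln = random_alignment(13, 30, rng)
        assign = {sid: ("A" if i < 5 else "B") for i, sid in enumerate(aln.ids)}
        pm = PopulationMap(assign)
        res = corrected_da(aln, pm)

        def ham(a, b):
            return sum(x != y for x, y in zip(a, b))

        xs = [s for sid, s in zip(aln.ids, aln.seqs) if assign[sid] == "A"]
        ys = [s for sid, s in zip(aln.ids, aln.seqs) if assign[sid] == "B"]
        pixy = np.mean([ham(a, b) for a in xs for b in ys])
        pix = np.mean([ham(a, b) for a, b in itertools.combinations(xs, 2)])
        piy = np.mean([ham(a, b) for a, b in itertools.combinations(ys, 2)])
        assert res.da[0, 1] == pytest.approx(pixy - (pix + piy) / 2, rel=1e-12)
        assert res.da[0, 1] == res.da[1, 0]

    def test_small_population_errors(self):
        aln, pm = _labelled({"X": ["AAAA"], "Y": ["TTTT", "TTTA"]})
        with pytest.raises(ValueError):
            corrected_da(aln, pm)


class TestBonferroni:
    def test_threshold_cases(self):
        p = np.array([0.004, 0.006, 0.2])
        flags = bonferroni_adjust(p, alpha=0.05)
        # m = 3 comparisons -> threshold 0.0167
        assert list(flags) == [True, True, False]

    def test_ten_comparisons(self):
        p = np.full(10, 0.006)
        p[0] = 0.004
        flags = bonferroni_adjust(p, alpha=0.05)
        assert flags[0] and not flags[1:].any()

    def test_single_comparison_is_raw(self):
        assert bonferroni_adjust(np.array([0.04]), alpha=0.05)[0]


class TestMantel:
    def _pair(self, k, rng):
        a = rng.uniform(1, 10, size=(k, k))
        a = np.triu(a, 1)
        a = a + a.T
        return a

    def test_affine_relation_r_one(self, rng):
        g = self._pair(5, rng)
        dm1 = DistanceMatrix(tuple("ABCDE"), g)
        dm2 = DistanceMatrix(tuple("ABCDE"), 2 * g)
        r, r2, p = mantel_test(dm1, dm2, permutations=99, seed=0)
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_exact_enumeration_unique_optimum(self, rng):
        g = self._pair(4, rng)
        noise = self._pair(4, rng) * 0.01
        dm1 = DistanceMatrix(tuple("ABCD"), g)
        dm2 = DistanceMatrix(tuple("ABCD"), g + noise)
        r, _, p = mantel_test(dm1, dm2, method="exact")
        # identity is the unique optimum among all 4! relabelings
        assert p == pytest.approx(1 / 24)

    def test_matches_skbio_r(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix as SkbioDM, mantel

        g1, g2 = self._pair(8, rng), self._pair(8, rng)
        labels = tuple("ABCDEFGH")
        r, _, _ = mantel_test(
            DistanceMatrix(labels, g1), DistanceMatrix(labels, g2),
            permutations=99, seed=0,
        )
        r_skbio = mantel(
            SkbioDM(g1, ids=labels), SkbioDM(g2, ids=labels),
            permutations=0,
        )[0]
        assert r == pytest.approx(float(r_skbio), rel=1e-10)

    def test_zero_variance_errors(self):
        labels = ("A", "B", "C")
        flat = np.ones((3, 3)) - np.eye(3)
        rng = np.random.default_rng(1)
        g = self._pair(3, rng)
        with pytest.raises(ValueError):
            mantel_test(DistanceMatrix(labels, flat), DistanceMatrix(labels, g))

    def test_calibration_under_independence(self):
        rng = np.random.default_rng(7)
        sims, rejections = 200, 0
        for _ in range(sims):
            g1, g2 = self._pair(10, rng), self._pair(10, rng)
            labels = tuple(f"L{i}" for i in range(10))
            _, _, p = mantel_test(
                DistanceMatrix(labels, g1), DistanceMatrix(labels, g2),
                permutations=99, seed=int(rng.integers(2**31)),
            )
            if p <= 0.05:
                rejections += 1
        assert 0.01 <= rejections / sims <= 0.10


class TestGreatCircle:
    def test_quarter_meridian(self):
        dm = great_circle_km({"eq": (0.0, 0.0), "pole": (90.0, 0.0)})
        assert dm.d[0, 1] == pytest.approx(6371.0 * np.pi / 2, rel=1e-6)
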