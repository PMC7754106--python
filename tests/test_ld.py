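"""EM haplotype LD: exact fixtures, counting oracle, EM properties."""

import itertools

import numpy as np
import pytest

from locuslens.ld import (
    InsufficientDataError,
    MonomorphicVariantError,
    counting_haplotypes,
    em_haplotypes,
    em_trajectory_loglik,
    find_proxies,
    ld_pair_report,
)

from conftest import panel_from_dosages


class TestExactFixtures:
    def test_identical_vectors_perfect_ld(self):
        g = np.array([0, 1, 2, 1, 0])
        stats = em_haplotypes(g, g)
        assert stats.r2 == pytest.approx(1.0, abs=1e-9)
        assert stats.d_prime == pytest.approx(1.0, abs=1e-9)
        assert stats.d > 0

    def test_perfect_repulsion(self):
        stats = em_haplotypes(np.array([0, 0, 2, 2]), np.array([2, 2, 0, 0]))
        assert stats.r2 == pytest.approx(1.0, abs=1e-9)
        assert stats.d_prime == pytest.approx(1.0, abs=1e-9)
        assert stats.d < 0

    def test_unambiguous_six_sample_fixture_matches_counting(self):
        # no double heterozygote: phase is fully determined
        ga = np.array([2, 2, 1, 0, 0, 1])
        gb = np.array([2, 2, 2, 0, 0, 0])
        em = em_haplotypes(ga, gb)
        direct = counting_haplotypes(ga, gb)
        assert em.hap_freqs == pytest.approx(direct.hap_freqs, abs=1e-9)
        assert em.d == pytest.approx(direct.d, abs=1e-9)
        assert em.r2 == pytest.approx(direct.r2, abs=1e-9)
        assert em.d_prime == pytest.approx(direct.d_prime, abs=1e-9)

    def test_haplotype_freqs_sum_to_one(self):
        rng = np.random.default_rng(5)
        ga = rng.integers(0, 3, 40)
        gb = rng.integers(0, 3, 40)
        stats = em_haplotypes(ga, gb)
        assert sum(stats.hap_freqs) == pytest.approx(1.0, abs=1e-9)
        assert 0 <= stats.r2 <= 1 and 0 <= stats.d_prime <= 1

    def test_r2_one_implies_dprime_one(self):
        g = np.array([0, 1, 2, 2, 0, 1, 1])
        stats = em_haplotypes(g, g)
        assert stats.r2 == pytest.approx(1.0, abs=1e-9)
        assert stats.d_prime == pytest.approx(1.0, abs=1e-9)


class TestErrors:
    def test_monomorphic_is_undefined_not_zero(self):
        with pytest.raises(MonomorphicVariantError):
            em_haplotypes(np.array([1, 1, 0, 2]), np.array([0, 0, 0, 0]))

    def test_all_na_overlap(self):
        ga = np.array([np.nan, np.nan, 1.0])
        gb = np.array([1.0, 1.0, np.nan])
        with pytest.raises(InsufficientDataError):
            em_haplotypes(ga, gb)

    def test_na_samples_dropped_pairwise(self):
        ga = np.array([0, 1, 2, 1, 0, np.nan])
        gb = np.array([0, 1, 2, 1, np.nan, 0])
        stats = em_haplotypes(ga, gb)
        assert stats.n == 4


class TestEMProperties:
    def enumerate_tables(self, n=4):
        """All genotype-pair assignments of n samples without double hets."""
        pairs = [(a, b) for a in range(3) for b in range(3) if (a, b) != (1, 1)]
        seen = set()
        for combo in itertools.combinations_with_replacement(pairs, n):
            if combo in seen:
                continue
            seen.add(combo)
            ga = np.array([c[0] for c in combo], dtype=float)
            gb = np.array([c[1] for c in combo], dtype=float)
            if 0 < ga.mean() < 2 and 0 < gb.mean() < 2:
                yield ga, gb

    def test_em_equals_counting_on_all_unambiguous_tables(self):
        n_checked = 0
        for ga, gb in self.enumerate_tables(4):
            em = em_haplotypes(ga, gb)
            direct = counting_haplotypes(ga, gb)
            assert em.hap_freqs == pytest.approx(direct.hap_freqs, abs=1e-6)
            assert em.r2 == pytest.approx(direct.r2, abs=1e-6)
            assert em.d_prime == pytest.approx(direct.d_prime, abs=1e-6)
            n_checked += 1
        assert n_checked > 100

    def test_loglik_monotone_nondecreasing(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            ga = rng.integers(0, 3, 30).astype(float)
            gb = rng.integers(0, 3, 30).astype(float)
            if not (0 < ga.mean() < 2 and 0 < gb.mean() < 2):
                continue
            traj = em_trajectory_loglik(ga, gb)
            assert all(b >= a - 1e-9 for a, b in zip(traj, traj[1:]))

    def test_allele_flip_and_symmetry(self):
        rng = np.random.default_rng(23)
        n_checked = 0
        while n_checked < 200:
            ga = rng.integers(0, 3, 24).astype(float)
            gb = rng.integers(0, 3, 24).astype(float)
            if not (0 < ga.mean() < 2 and 0 < gb.mean() < 2):
                continue
            base = em_haplotypes(ga, gb)
            flipped = em_haplotypes(2 - ga, gb)
            assert flipped.d == pytest.approx(-base.d, abs=1e-9)
            assert flipped.r2 == pytest.approx(base.r2, abs=1e-9)
            assert flipped.d_prime == pytest.approx(base.d_prime, abs=1e-9)
            swapped = em_haplotypes(gb, ga)
            assert swapped.r2 == pytest.approx(base.r2, abs=1e-9)
            assert swapped.d_prime == pytest.approx(base.d_prime, abs=1e-9)
            n_checked += 1


class TestPairReportAndProxies:
    def test_self_ld_is_one(self):
        panel = panel_from_dosages(np.array([[0, 0], [1, 1], [2, 2], [1, 1]]))
        stats = ld_pair_report("v0", "v1", panel)
        assert stats.r2 == pytest.approx(1.0, abs=1e-9)

    def test_report_symmetric(self):
        rng = np.random.default_rng(2)
        panel = panel_from_dosages(rng.integers(0, 3, size=(30, 2)))
        ab = ld_pair_report("v0", "v1", panel)
        ba = ld_pair_report("v1", "v0", panel)
        assert ab.r2 == pytest.approx(ba.r2, abs=1e-9)
        assert ab.d_prime == pytest.approx(ba.d_prime, abs=1e-9)

    def test_duplicate_variant_found_first(self):
        g = np.array([0, 1, 2, 1, 0, 2, 1, 0])
        rng = np.random.default_rng(3)
        other = rng.integers(0, 3, 8)
        panel = panel_from_dosages(np.column_stack([g, g, other]), ids=["target", "twin", "noise"])
        out = find_proxies("target", panel)
        assert out[0][0] == "twin"
        assert out[0][1].r2 == pytest.approx(1.0, abs=1e-9)

    def test_independent_variants_give_no_proxies(self):
        rng = np.random.default_rng(11)
        panel = panel_from_dosages(rng.binomial(2, 0.4, size=(200, 20)))
        assert find_proxies("v0", panel) == []

    def test_strict_threshold_r2min_one(self):
        rng = np.random.default_rng(4)
        g = rng.integers(0, 3, 50)
        noisy = g.copy()
        noisy[:5] = 2 - noisy[:5]
        panel = panel_from_dosages(np.column_stack([g, noisy]), ids=["t", "near"])
        # r2 < 1 for the perturbed partner, and strictly-greater-than-1 is empty
        assert find_proxies("t", panel, r2_min=1.0) == []

    def test_absent_target_raises(self):
        panel = panel_from_dosages(np.array([[0, 1], [1, 2]]))
        with pytest.raises(KeyError):
            find_proxies("missing", panel)

    def test_proxies_sorted_by_r2_then_pos(self):
        g = np.array([0, 1, 2, 1, 0, 2, 1, 0, 2, 0])
        near = g.copy()
        near[0] = 1  # slightly degraded LD
        panel = panel_from_dosages(
            np.column_stack([g, near, g]), ids=["t", "near", "twin"], pos=[100, 200, 300]
        )
        out = find_proxies("t", panel)
        assert [vid for vid, _ in out] == ["twin", "near"]
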