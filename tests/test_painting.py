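"""Copying-model posteriors against an exhaustive path-sum oracle, and the
Weir–Cockerham Fst estimator against independent arithmetic."""

import itertools

import numpy as np
import pytest

from rohpaint.genotype_io import GenotypeMatrix
from rohpaint.painting import (CopyingModelParams, average_ancestry,
                               miscopy_probability, paint_haplotype,
                               paint_population, watterson_theta,
                               weir_cockerham_fst)
from rohpaint.synthetic_data import SimConfig, simulate_composite

from conftest import toy_genotypes, toy_marker_map


# ---------------------------------------------------------------------------
# exhaustive path-sum oracle for the copying HMM
# ---------------------------------------------------------------------------

def oracle_posteriors(recipient, donors, cm, rho, mu):
    K, n = donors.shape
    emit = np.where(donors == recipient[None, :], 1 - mu, mu)
    stay = np.exp(-rho * np.diff(cm))
    post = np.zeros((n, K))
    total = 0.0
    for path in itertools.product(range(K), repeat=n):
        p = emit[path[0], 0] / K
        for t in range(1, n):
            trans = (1 - stay[t - 1]) / K
            if path[t] == path[t - 1]:
                trans += stay[t - 1]
            p *= trans * emit[path[t], t]
        total += p
        for t, k in enumerate(path):
            post[t, k] += p
    return post / total, np.log(total)


@pytest.mark.parametrize("K,n,seed", [(2, 3, 0), (2, 6, 1), (3, 5, 2),
                                      (3, 8, 3)])
def test_forward_backward_equals_path_sum(K, n, seed):
    rng = np.random.default_rng(seed)
    recipient = rng.integers(0, 2, n).astype(np.int8)
    donors = rng.integers(0, 2, (K, n)).astype(np.int8)
    cm = np.cumsum(rng.uniform(0.01, 2.0, n))
    rho, mu = 0.8, 0.1
    groups = [f"d{k}" for k in range(K)]  # one group per donor: donor posteriors
    prof = paint_haplotype(recipient, donors, groups, cm,
                           CopyingModelParams(rho=rho, mu=mu))
    expect, loglik = oracle_posteriors(recipient, donors, cm, rho, mu)
    assert np.allclose(prof.probs, expect, atol=1e-10)
    assert prof.log_likelihood == pytest.approx(loglik)


class TestPaintingProperties:
    def test_single_group_panel_gives_probability_one(self):
        rng = np.random.default_rng(4)
        donors = rng.integers(0, 2, (5, 20)).astype(np.int8)
        prof = paint_haplotype(rng.integers(0, 2, 20).astype(np.int8), donors,
                               ["A"] * 5, np.arange(20) * 0.1)
        assert np.allclose(prof.group_prob("A"), 1.0)

    def test_posterior_concentrates_on_identical_donor(self):
        rng = np.random.default_rng(5)
        donors = rng.integers(0, 2, (4, 30)).astype(np.int8)
        recipient = donors[2].copy()
        prof = paint_haplotype(recipient, donors,
                               ["A", "A", "B", "B"], np.arange(30) * 0.5,
                               CopyingModelParams(rho=1e-6, mu=1e-9))
        assert np.all(prof.group_prob("B") > 0.999)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(6)
        donors = rng.integers(0, 2, (6, 40)).astype(np.int8)
        prof = paint_haplotype(rng.integers(0, 2, 40).astype(np.int8), donors,
                               ["A", "B", "A", "B", "A", "B"],
                               np.cumsum(rng.uniform(0.01, 1, 40)))
        assert np.allclose(prof.probs.sum(axis=1), 1.0, atol=1e-8)
        assert np.all((prof.probs >= 0) & (prof.probs <= 1))

    def test_invariant_under_within_breed_relabeling(self):
        rng = np.random.default_rng(7)
        donors = rng.integers(0, 2, (6, 25)).astype(np.int8)
        recipient = rng.integers(0, 2, 25).astype(np.int8)
        cm = np.arange(25) * 0.3
        labels = ["A", "A", "A", "B", "B", "B"]
        p1 = paint_haplotype(recipient, donors, labels, cm)
        perm = [2, 0, 1, 5, 3, 4]  # permute donors within each breed
        p2 = paint_haplotype(recipient, donors[perm],
                             [labels[i] for i in perm], cm)
        assert np.allclose(p1.group_prob("A"), p2.group_prob("A"), atol=1e-12)

    def test_watterson_theta_and_mu(self):
        assert watterson_theta(2) == pytest.approx(1.0)
        assert watterson_theta(5) == pytest.approx(1 / (1 + 0.5 + 1 / 3 + 0.25))
        K = 10
        th = watterson_theta(K)
        assert miscopy_probability(K) == pytest.approx(th / (2 * (K + th)))

    def test_exchangeable_founders_paint_at_chance(self):
        cfg = SimConfig(n_chromosomes=1, n_markers_per_chrom=400,
                        chrom_length=20_000_000, fst_a=0.0, fst_b=0.0,
                        n_founders_a=12, n_founders_b=12, n_composite=12,
                        n_generations=3, seed=21)
        sim = simulate_composite(cfg)
        profs = paint_population(sim.haplotypes, "composite",
                                 ["founderA", "founderB"])
        mean_a = np.mean([p.group_prob("founderA").mean() for p in profs])
        # equal panels: breed probability hovers at the 0.5 panel prior
        assert mean_a == pytest.approx(0.5, abs=0.05)

    def test_average_ancestry_symmetry_and_identity(self, small_sim):
        profs = paint_population(small_sim.haplotypes, "composite",
                                 ["founderA", "founderB"])[:2]
        m = small_sim.haplotypes.markers
        snp, region = average_ancestry([profs[0]], m)
        assert np.allclose(snp["p_founderA"], profs[0].group_prob("founderA"))
        two, _ = average_ancestry(profs, m)
        assert np.allclose(
            two["p_founderA"],
            (profs[0].group_prob("founderA")
             + profs[1].group_prob("founderA")) / 2)


# ---------------------------------------------------------------------------
# Weir & Cockerham Fst
# ---------------------------------------------------------------------------

def _two_pop_matrix(calls1, calls2, n_markers):
    calls = np.vstack([calls1, calls2]).astype(np.int8)
    pops = ["p1"] * len(calls1) + ["p2"] * len(calls2)
    return toy_genotypes(calls, np.arange(n_markers) * 1000 + 1, pops=pops)


class TestWeirCockerham:
    def test_fixed_difference_near_one(self):
        g = _two_pop_matrix(np.full((10, 5), 2), np.zeros((10, 5)), 5)
        assert weir_cockerham_fst(g, ("p1", "p2")).estimate == pytest.approx(1.0)

    def test_null_simulation_small(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(0.1, 0.9, 10_000)
        calls1 = rng.binomial(2, p, (20, 10_000))
        calls2 = rng.binomial(2, p, (20, 10_000))
        g = _two_pop_matrix(calls1, calls2, 10_000)
        assert weir_cockerham_fst(g, ("p1", "p2")).estimate < 0.05

    def test_hand_worked_single_snp(self):
        # pop1: 8 hom-alt + 2 het (p=0.9, h=0.2); pop2 mirrored (p=0.1)
        calls1 = np.array([[2]] * 8 + [[1]] * 2)
        calls2 = np.array([[0]] * 8 + [[1]] * 2)
        g = _two_pop_matrix(calls1, calls2, 1)
        res = weir_cockerham_fst(g, ("p1", "p2"))
        # independent arithmetic, straight from the 1984 component formulas
        n1 = n2 = 10.0
        p1, p2, h1, h2, r = 0.9, 0.1, 0.2, 0.2, 2.0
        nbar = (n1 + n2) / r
        nc = ((n1 + n2) - (n1 ** 2 + n2 ** 2) / (n1 + n2)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
        assert res.a[0] == pytest.approx(a)
        assert res.b[0] == pytest.approx(b)
        assert res.c[0] == pytest.approx(c)
        assert res.estimate == pytest.approx(a / (a + b + c))
        assert res.estimate == pytest.approx(0.7696, abs=1e-4)

    def test_monomorphic_contributes_nothing(self):
        calls1 = np.hstack([np.full((10, 1), 2), np.full((10, 1), 2)])
        calls2 = np.hstack([np.zeros((10, 1)), np.full((10, 1), 2)])
        g = _two_pop_matrix(calls1, calls2, 2)
        res = weir_cockerham_fst(g, ("p1", "p2"))
        assert res.a[1] == res.b[1] == res.c[1] == 0.0

    def test_too_few_samples_error(self):
        g = _two_pop_matrix(np.full((1, 3), 2), np.zeros((3, 3)), 3)
        with pytest.raises(ValueError):
            weir_cockerham_fst(g, ("p1", "p2"))

    def test_fst_increases_with_founder_divergence(self):
        from scipy.stats import spearmanr
        grid = [0.02, 0.05, 0.1, 0.2, 0.3]
        ests = []
        for fst in grid:
            cfg = SimConfig(n_chromosomes=1, n_markers_per_chrom=600,
                            chrom_length=20_000_000, fst_a=fst, fst_b=fst,
                            n_founders_a=15, n_founders_b=15, n_composite=4,
                            n_generations=1, n_sires_per_gen=2, seed=33)
            sim = simulate_composite(cfg)
            ests.append(weir_cockerham_fst(
                sim.genotypes, ("founderA", "founderB")).estimate)
        rho, _ = spearmanr(grid, ests)
        assert rho > 0.9
        assert all(e2 > e1 for e1, e2 in zip(ests, ests[1:]))
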