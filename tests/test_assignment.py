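"""Admixture estimation, hybrid thresholds and assignment likelihoods."""

import math

import numpy as np
import pytest
from scipy import stats

import seedsource as ss
from seedsource.assignment import rannala_mountain_loglik


def diagnostic_pools(n=60, n_loci=13, seed=0):
    """Two pools fixed for disjoint allele sets at every locus."""
    rng = np.random.default_rng(seed)
    calls_a = np.zeros((n, n_loci, 2), int)
    calls_b = np.zeros((n, n_loci, 2), int)
    for l in range(n_loci):
        a_alleles = np.arange(100, 104)
        b_alleles = np.arange(200, 204)
        calls_a[:, l, :] = rng.choice(a_alleles, size=(n, 2))
        calls_b[:, l, :] = rng.choice(b_alleles, size=(n, 2))
    mk = lambda calls, g: ss.GenotypeTable.from_calls(
        [f"{g}{k}" for k in range(n)], [f"L{l}" for l in range(n_loci)], calls, [g] * n
    )
    return mk(calls_a, "A"), mk(calls_b, "B")


class TestClassifyVariety:
    @pytest.mark.parametrize(
        "q,expected",
        [(0.85, "coastal"), (0.15, "interior"), (0.5, "hybrid"),
         (0.80, "hybrid"), (0.20, "hybrid")],
    )
    def test_thresholds_with_hybrid_boundaries(self, q, expected):
        assert ss.classify_variety(q) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ss.classify_variety(1.2)


class TestSupervisedQ:
    def test_private_alleles_drive_q_to_one(self):
        pool_a, pool_b = diagnostic_pools()
        fa, fb = pool_a.allele_frequencies(), pool_b.allele_frequencies()
        q, ll, _ = ss.supervised_q(pool_a.calls[0], fa, fb)
        assert q > 0.999

    def test_identical_pools_flat_likelihood_returns_half(self):
        pool_a, _ = diagnostic_pools()
        fa = pool_a.allele_frequencies()
        q, _, it = ss.supervised_q(pool_a.calls[0], fa, fa)
        assert q == pytest.approx(0.5)

    def test_label_swap_symmetry(self, metapop):
        fa = metapop.table.allele_frequencies("R01")
        fb = metapop.table.allele_frequencies("R30")
        for i in range(0, 60, 7):
            q1, _, _ = ss.supervised_q(metapop.table.calls[i], fa, fb)
            q2, _, _ = ss.supervised_q(metapop.table.calls[i], fb, fa)
            assert q1 + q2 == pytest.approx(1.0, abs=1e-4)

    def test_matches_grid_search(self, metapop):
        """EM optimum equals a fine 1D grid search of the mixture likelihood."""
        fa = metapop.table.allele_frequencies("R01")
        fb = metapop.table.allele_frequencies("R30")
        rng = np.random.default_rng(1)
        grid = np.linspace(0.0, 1.0, 20001)
        for i in rng.choice(len(metapop.table), size=100, replace=False):
            q_em, ll_em, _ = ss.supervised_q(metapop.table.calls[i], fa, fb, tol=1e-10)
            # grid oracle on the same floored per-copy frequencies
            pa, pb = [], []
            for l in range(metapop.table.n_loci):
                a1, a2 = metapop.table.calls[i, l]
                if a1 == 0:
                    continue
                alleles = sorted(set(fa.freqs[l]) | set(fb.freqs[l]) | {int(a1), int(a2)})
                from seedsource.assignment import _floored

                f_a = _floored(fa.freqs[l], alleles, 0.01)
                f_b = _floored(fb.freqs[l], alleles, 0.01)
                for a in (a1, a2):
                    pa.append(f_a[int(a)])
                    pb.append(f_b[int(a)])
            pa, pb = np.array(pa), np.array(pb)
            lls = np.log(grid[:, None] * pa + (1 - grid[:, None]) * pb).sum(axis=1)
            q_grid = grid[np.argmax(lls)]
            assert q_em == pytest.approx(q_grid, abs=1e-4)

    def test_f1_q_near_half(self):
        """F1s between diagnostic pools score as admixed (Q around 0.5)."""
        pool_a, pool_b = diagnostic_pools()
        fa, fb = pool_a.allele_frequencies(), pool_b.allele_frequencies()
        f1 = ss.simulate_f1(pool_a, pool_b, n_f1=500, seed=3)
        res = ss.AdmixtureModel(f1, fa, fb, min_loci=1).fit()
        qs = res.frame()["Qvar"].to_numpy()
        assert np.mean((qs >= 0.35) & (qs <= 0.65)) >= 0.95


class TestSimulateF1:
    def test_fixed_cross_always_heterozygous(self):
        calls_a = np.full((10, 1, 2), 90)
        calls_b = np.full((10, 1, 2), 100)
        mk = lambda c, g: ss.GenotypeTable.from_calls(
            [f"{g}{k}" for k in range(10)], ["L1"], c, [g] * 10
        )
        f1 = ss.simulate_f1(mk(calls_a, "A"), mk(calls_b, "B"), n_f1=20, seed=0)
        assert (np.sort(f1.calls[:, 0, :], axis=1) == [90, 100]).all()

    def test_gamete_frequencies_match_pools(self, metapop):
        """F1 maternal-gamete allele frequencies reproduce pool frequencies."""
        pool_a = metapop.table.subset(group="R01")
        pool_b = metapop.table.subset(group="R30")
        f1 = ss.simulate_f1(pool_a, pool_b, n_f1=10_000, seed=4)
        fa = pool_a.allele_frequencies()
        for l in (0, 5, 12):
            gametes = f1.calls[:, l, 0]  # first allele drawn from pool A
            alleles = np.array(sorted(fa.freqs[l]))
            obs = np.array([(gametes == a).sum() for a in alleles])
            exp = np.array([fa.freqs[l][int(a)] for a in alleles]) * len(f1)
            keep = exp > 1
            chi2 = ((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum()
            assert stats.chi2.sf(chi2, keep.sum() - 1) > 0.001

    def test_seeded_reproducibility(self, metapop):
        a = metapop.table.subset(group="R01")
        b = metapop.table.subset(group="R30")
        f1x = ss.simulate_f1(a, b, n_f1=30, seed=7)
        f1y = ss.simulate_f1(a, b, n_f1=30, seed=7)
        assert np.array_equal(f1x.calls, f1y.calls)


class TestCalibrateThresholds:
    def test_pooled_row_is_sum_and_replicates_differ(self):
        pool_a, pool_b = diagnostic_pools(n=40)
        df = ss.calibrate_thresholds(pool_a, pool_b, n_f1=40, replicates=3, seed=5)
        pooled = df[df["replicate"] == "pooled"]
        reps = df[df["replicate"] != "pooled"]
        for cls in ("coastal", "hybrid", "interior"):
            block = reps[reps["true_class"] == cls]
            assert pooled[pooled["true_class"] == cls]["hybrid"].iloc[0] == block["hybrid"].sum()

    def test_identical_pools_hybrid_recall_at_chance(self):
        pool_a, _ = diagnostic_pools(n=40)
        df = ss.calibrate_thresholds(pool_a, pool_a, n_f1=40, replicates=2, seed=6)
        pooled = df[(df["replicate"] == "pooled") & (df["true_class"] == "hybrid")]
        # no signal: everything sits at the flat-likelihood value 0.5 = hybrid band
        assert pooled["hybrid"].iloc[0] == pooled["n"].iloc[0]


class TestAssignmentLikelihoods:
    def test_paetkau_single_locus_het(self):
        t = ss.GenotypeTable.from_calls(
            ["r1", "r2"], ["L1"], np.array([[[90, 100]], [[90, 100]]]), ["R", "R"]
        )
        ref = t.allele_frequencies("R")
        ll = ss.paetkau_loglik(np.array([[90, 100]]), ref)
        assert ll == pytest.approx(math.log(0.5))

    def test_paetkau_unseen_allele_uses_floor(self):
        t = ss.GenotypeTable.from_calls(
            ["r1", "r2"], ["L1"], np.array([[[90, 90]], [[90, 90]]]), ["R", "R"]
        )
        ref = t.allele_frequencies("R")
        ll = ss.paetkau_loglik(np.array([[100, 100]]), ref, floor=0.01)
        # floored: p(100) = 0.01/1.01; genotype prob = p^2
        assert ll == pytest.approx(2 * math.log(0.01 / 1.01))
        assert math.isfinite(ll)

    def test_rannala_hand_values(self):
        # n=2 copies of allele A only, k=2, genotype BB
        ll = rannala_mountain_loglik(np.array([[100, 100]]), [{90: 2.0}], [2])
        assert math.exp(ll) == pytest.approx(0.0625)
        # empty reference, k=2, het AB: 2 * 0.5 * 0.5 / (1 * 2) = 0.25
        ll = rannala_mountain_loglik(np.array([[90, 100]]), [{}], [2])
        assert math.exp(ll) == pytest.approx(0.25)

    def test_rannala_converges_to_paetkau_for_large_reference(self):
        """With huge reference counts the Bayesian measure matches the
        frequency-based one (no floor needed)."""
        rng = np.random.default_rng(8)
        freqs = {90: 0.5, 100: 0.3, 110: 0.2}
        n = 200_000
        counts = [{a: p * n for a, p in freqs.items()}]
        for geno in ([[90, 90]], [[90, 100]], [[110, 110]]):
            calls = np.array(geno)
            ll_rm = rannala_mountain_loglik(calls, counts, [3])
            a1, a2 = calls[0]
            p_exact = (
                freqs[a1] ** 2 if a1 == a2 else 2 * freqs[a1] * freqs[a2]
            )
            assert ll_rm == pytest.approx(math.log(p_exact), abs=1e-2)


class TestAssign:
    def test_scores_sum_to_hundred(self, metapop):
        res = ss.assign(metapop.table.subset(group="R01"), metapop.table, "rannala")
        np.testing.assert_allclose(res.scores.sum(axis=1), 100.0, atol=1e-9)

    def test_identical_references_split_evenly(self):
        pool_a, _ = diagnostic_pools(n=20)
        twin = ss.GenotypeTable.from_calls(
            [f"c{k}" for k in range(20)],
            [l.name for l in pool_a.loci],
            pool_a.calls.copy(),
            ["A2"] * 20,
        )
        refs = ss.concat_tables([pool_a, twin])
        res = ss.assign(pool_a, refs, "paetkau", min_loci=1)
        np.testing.assert_allclose(res.scores["A"], res.scores["A2"], atol=1e-9)

    @pytest.mark.parametrize("measure", ["paetkau", "rannala"])
    def test_self_assignment_dominance(self, diagnostic_metapop, measure):
        """Individuals simulated from a reference assign back to it."""
        from seedsource.simulate import _draw_genotypes

        m = diagnostic_metapop
        rng = np.random.default_rng(77)
        hits = total = 0
        for pop in ("R01", "R10", "R19", "R28"):
            calls = _draw_genotypes(rng, m.pop_freqs[pop], m.allele_codes, 30)
            query = ss.GenotypeTable.from_calls(
                [f"q{k}" for k in range(30)],
                [l.name for l in m.table.loci],
                calls,
                [pop] * 30,
            )
            res = ss.assign(query, m.table, measure)
            best = res.scores.idxmax(axis=1)
            hits += (best == pop).sum()
            total += len(best)
        assert hits / total >= 0.9
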