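"""Parentage LOD scores, simulated confidence, dispersal distances."""

import math

import numpy as np
import pytest

import seedsource as ss
from seedsource.parentage import (
    CriticalDeltas,
    ParentageModel,
    _critical_from_deltas,
    dispersal_distances,
    lod_single_parent,
)


def freqs_from(freq_dicts):
    """AlleleFrequencies stub from explicit per-locus frequency dicts."""
    from seedsource.genotypes import AlleleFrequencies, Locus

    loci = [Locus(f"L{i}", tuple(d)) for i, d in enumerate(freq_dicts)]
    copies = np.full(len(freq_dicts), 100)
    return AlleleFrequencies(loci, [dict(d) for d in freq_dicts], copies)


class TestLodSingleParent:
    def test_hand_value_shared_homozygote(self):
        # offspring AA, candidate AA, p(A) = 0.5: T = 0.5, P = 0.25, LOD = ln 2
        f = freqs_from([{90: 0.5, 100: 0.5}])
        lod, shared, mm = lod_single_parent(
            np.array([[90, 90]]), np.array([[90, 90]]), f, error=0.0, min_loci=1
        )
        assert lod == pytest.approx(math.log(2))
        assert (shared, mm) == (1, 0)

    def test_mendelian_exclusion_at_zero_error(self):
        f = freqs_from([{90: 0.5, 100: 0.5}])
        lod, _, mm = lod_single_parent(
            np.array([[90, 90]]), np.array([[100, 100]]), f, error=0.0, min_loci=1
        )
        assert lod == -math.inf and mm == 1

    def test_error_model_forgives_exclusion(self):
        f = freqs_from([{90: 0.5, 100: 0.5}])
        lod, _, _ = lod_single_parent(
            np.array([[90, 90]]), np.array([[100, 100]]), f, error=0.01, min_loci=1
        )
        assert math.isfinite(lod) and lod < 0

    def test_additive_and_order_invariant(self):
        rng = np.random.default_rng(0)
        f = freqs_from([{90: 0.4, 100: 0.35, 110: 0.25}] * 6)
        off = rng.choice([90, 100, 110], size=(6, 2))
        cand = rng.choice([90, 100, 110], size=(6, 2))
        lod, _, _ = lod_single_parent(off, cand, f, error=0.01, min_loci=1)
        total = sum(
            lod_single_parent(off[l : l + 1], cand[l : l + 1], f, 0.01, 1)[0]
            for l in range(6)
        )
        assert lod == pytest.approx(total)
        perm = rng.permutation(6)
        lod_p, _, _ = lod_single_parent(off[perm], cand[perm], f, error=0.01, min_loci=1)
        assert lod_p == pytest.approx(lod)

    def test_error_shrinks_per_locus_lod_toward_zero(self):
        """Each locus log-ratio moves monotonically toward 0 as e grows."""
        rng = np.random.default_rng(1)
        f = freqs_from([{90: 0.5, 100: 0.3, 110: 0.2}])
        for _ in range(30):
            off = rng.choice([90, 100, 110], size=(1, 2))
            cand = rng.choice([90, 100, 110], size=(1, 2))
            prev = None
            for e in (0.001, 0.01, 0.05, 0.2):
                lod, _, _ = lod_single_parent(off, cand, f, error=e, min_loci=1)
                if prev is not None and math.isfinite(prev):
                    assert abs(lod) <= abs(prev) + 1e-12
                prev = lod

    def test_min_loci_enforced(self):
        f = freqs_from([{90: 0.5, 100: 0.5}])
        with pytest.raises(ValueError, match="shared"):
            lod_single_parent(np.array([[90, 90]]), np.array([[90, 90]]), f, min_loci=2)


class TestSimulateConfidence:
    def test_perfect_information_limit(self):
        """Diagnostic loci, all parents sampled: every assignment correct."""
        f = freqs_from([{a: 1 / 8 for a in range(100 + 10 * l, 180 + 10 * l, 10)} for l in range(10)])
        crit = ss.simulate_confidence(
            f, n_offspring=150, prop_parents_sampled=1.0, n_candidates=10,
            error=1e-6, min_loci=9, seed=0,
        )
        assert crit.assignment_rate_strict == 1.0
        assert crit.assignment_rate_relaxed == 1.0

    def test_single_weak_locus_success_matches_enumeration(self):
        """One biallelic locus: recovery equals the exact closed-form
        expectation (slightly above 1/n_candidates because Mendelian
        exclusion still removes some incompatible candidates)."""
        f = freqs_from([{90: 0.5, 100: 0.5}])
        genos = [(90, 90), (90, 100), (100, 100)]
        hwe = {(90, 90): 0.25, (90, 100): 0.5, (100, 100): 0.25}
        n_cand = 5

        def lod(o, c):
            return lod_single_parent(
                np.array([o]), np.array([c]), f, error=0.01, min_loci=1
            )[0]

        def offspring_dist(m, fa):
            out = {}
            for a in m:
                for b in fa:
                    g = tuple(sorted((a, b)))
                    out[g] = out.get(g, 0) + 0.25
            return out

        # oracle: P(true parent wins argmax with first-index tie-breaking)
        expected = 0.0
        for m in genos:
            for fa in genos:
                for off, p_off in offspring_dist(m, fa).items():
                    lods = {g: lod(off, g) for g in genos}
                    lm = lods[m]
                    h = sum(hwe[g] for g in genos if lods[g] > lm + 1e-12)
                    s = sum(hwe[g] for g in genos if abs(lods[g] - lm) <= 1e-12)
                    w = 1.0 - h - s
                    # E[1/(1+X)], X ~ Binom(n-1, s), and nobody strictly higher
                    win = ((s + w) ** n_cand - w**n_cand) / (n_cand * s)
                    expected += hwe[m] * hwe[fa] * p_off * win

        rng = np.random.default_rng(2)
        from seedsource.parentage import _mate, _sample_genotype

        correct = []
        for _ in range(2000):
            mother = _sample_genotype(rng, f)
            father = _sample_genotype(rng, f)
            off = _mate(rng, mother, father)
            cands = [_sample_genotype(rng, f) for _ in range(n_cand - 1)]
            idx = int(rng.integers(n_cand))
            cands.insert(idx, mother)
            lods = [lod_single_parent(off, c, f, 0.01, 1)[0] for c in cands]
            correct.append(int(np.argmax(lods)) == idx)
        assert np.mean(correct) == pytest.approx(expected, abs=0.035)
        assert expected < 0.35  # far below the informative-panel accuracy

    def test_seeded_runs_reproducible(self, metapop):
        f = metapop.table.allele_frequencies("R01")
        a = ss.simulate_confidence(f, n_offspring=60, n_candidates=10, seed=5)
        b = ss.simulate_confidence(f, n_offspring=60, n_candidates=10, seed=5)
        assert (a.strict95, a.relaxed80) == (b.strict95, b.relaxed80)

    def test_critical_delta_orders_strict_above_relaxed(self):
        deltas = np.linspace(0, 10, 200)
        correct = deltas > 3  # accuracy improves with Delta
        d95, _ = _critical_from_deltas(deltas, correct, 0.95)
        d80, _ = _critical_from_deltas(deltas, correct, 0.80)
        assert d95 >= d80


class TestAssignParents:
    def test_strict_subset_of_relaxed_and_exclusion_handling(self, stand):
        model = ParentageModel(stand.offspring, stand.adults, error=0.01)
        crit = CriticalDeltas(2.0, 0.5, 0.95, 0.8, 0)
        res = model.fit(crit)
        df = res.frame()
        assert set(a.offspring for a in res.strict()) <= set(
            a.offspring for a in res.relaxed()
        )
        assert (df.loc[[a.offspring for a in res.strict()], "Delta"] >= 2.0).all()

    def test_recovers_true_parents(self, stand):
        """Most confident assignments name the true mother or father."""
        model = ParentageModel(stand.offspring, stand.adults, error=0.01)
        crit = model.simulate_confidence(
            n_offspring=400, prop_parents_sampled=0.8, seed=3
        )
        res = model.fit(crit)
        strict = res.strict()
        assert len(strict) >= 5
        truth = {
            o: {stand.mothers[o], stand.fathers[o]} for o in stand.mothers
        }
        correct = sum(a.candidate in truth[a.offspring] for a in strict)
        assert correct / len(strict) >= 0.8

    def test_repeated_parent_appears_per_offspring(self, stand):
        model = ParentageModel(stand.offspring, stand.adults, error=0.01)
        res = model.fit(CriticalDeltas(0.0, 0.0, 1.0, 1.0, 0))
        counts = res.frame()["candidate"].value_counts()
        assert counts.sum() == len(stand.offspring)  # one row per offspring


class TestDispersal:
    def _results(self, pairs):
        from seedsource.parentage import ParentageAssignment, ParentageResults

        assignments = [
            ParentageAssignment(o, c, 5.0, 3.0, "strict95", 0) for o, c in pairs
        ]
        return ParentageResults(assignments, CriticalDeltas(1.0, 0.5, 0.95, 0.8, 0))

    def test_three_four_five(self):
        coords = ss.CoordinateSet(["p", "o"], np.array([[0.0, 0.0], [3.0, 4.0]]))
        s = dispersal_distances(self._results([("o", "p")]), coords)
        assert s.distances["stand"] == [pytest.approx(5.0)]

    def test_coincident_points_and_minmax(self):
        coords = ss.CoordinateSet(
            ["p", "o1", "o2", "o3"],
            np.array([[0.0, 0.0], [0.0, 0.0], [2.5, 0.0], [0.0, 92.0]]),
        )
        s = dispersal_distances(
            self._results([("o1", "p"), ("o2", "p"), ("o3", "p")]), coords
        )
        assert s.minmax()["stand"] == (pytest.approx(0.0), pytest.approx(92.0))

    def test_missing_coordinates_skipped(self):
        coords = ss.CoordinateSet(["p"], np.array([[0.0, 0.0]]))
        s = dispersal_distances(self._results([("o", "p")]), coords)
        assert s.distances == {}
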