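"""Single-parent likelihood parentage with simulated confidence.

For each offspring the most likely single parent among the genotyped
adults is found by a LOD score summing, over shared loci, the log ratio of
the Mendelian single-parent transition probability (with the untransmitted
allele drawn from population allele frequencies, and a genotyping-error
blend) to the unconditional HWE genotype probability.  Confidence in an
assignment rests on Delta, the LOD gap between the best and second-best
candidate; critical Delta values at the strict (95%) and relaxed (80%)
levels are obtained by simulating mating events from the population's
allele frequencies.  Assigned parent-offspring pairs with coordinates
yield realized propagule (pollen/seed) dispersal distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, AlleleFrequencies, CoordinateSet, GenotypeTable

DEFAULT_ERROR = 0.01
DEFAULT_MIN_LOCI = 9


def _transition_prob(go: tuple[int, int], gc: tuple[int, int], freqs: dict[int, float]) -> float:
    """Mendelian P(offspring genotype | single parent genotype).

    The candidate transmits one of its two alleles with probability 1/2;
    the other offspring allele comes from the population gene pool.
    """
    a, b = go
    pa, pb = freqs.get(a, 0.0), freqs.get(b, 0.0)
    t = 0.0
    for transmitted in gc:
        if a == b:
            t += 0.5 * (pa if transmitted == a else 0.0)
        else:
            if transmitted == a:
                t += 0.5 * pb
            elif transmitted == b:
                t += 0.5 * pa
    return t


def _hwe_prob(go: tuple[int, int], freqs: dict[int, float]) -> float:
    a, b = go
    pa, pb = freqs.get(a, 0.0), freqs.get(b, 0.0)
    return pa * pa if a == b else 2.0 * pa * pb


def lod_single_parent(
    offspring_calls: np.ndarray,
    candidate_calls: np.ndarray,
    pop_freqs: AlleleFrequencies,
    error: float = DEFAULT_ERROR,
    min_loci: int = DEFAULT_MIN_LOCI,
) -> tuple[float, int, int]:
    """LOD of a candidate single parent for one offspring.

    LOD = sum over shared loci of ln(T_e / P(g_o)) with the error blend
    T_e = (1-e)^2 T + (1 - (1-e)^2) P(g_o); at e = 0 a Mendelian exclusion
    yields -inf.  Returns (lod, n_shared_loci, n_mismatches) where a
    mismatch is a locus with Mendelian transition probability 0.

    Raises ValueError when fewer than ``min_loci`` loci are genotyped in
    both individuals.
    """
    lod = 0.0
    shared = 0
    mismatches = 0
    blend = (1.0 - error) ** 2
    for l in range(offspring_calls.shape[0]):
        go = (int(offspring_calls[l, 0]), int(offspring_calls[l, 1]))
        gc = (int(candidate_calls[l, 0]), int(candidate_calls[l, 1]))
        if go[0] == MISSING or gc[0] == MISSING:
            continue
        shared += 1
        freqs = pop_freqs.freqs[l]
        t = _transition_prob(go, gc, freqs)
        p = _hwe_prob(go, freqs)
        if t == 0.0:
            mismatches += 1
        te = blend * t + (1.0 - blend) * p
        if te == 0.0:
            lod = -math.inf
        elif p > 0.0 and math.isfinite(lod):
            lod += math.log(te / p)
    if shared < min_loci:
        raise ValueError(f"only {shared} shared genotyped loci (< {min_loci})")
    return lod, shared, mismatches


@dataclass
class CriticalDeltas:
    strict95: float
    relaxed80: float
    assignment_rate_strict: float
    assignment_rate_relaxed: float
    n_simulated: int


def _sample_genotype(rng: np.random.Generator, freqs: AlleleFrequencies) -> np.ndarray:
    L = freqs.n_loci
    calls = np.zeros((L, 2), dtype=int)
    for l in range(L):
        alleles = np.array(list(freqs.freqs[l]))
        p = np.array(list(freqs.freqs[l].values()))
        calls[l] = rng.choice(alleles, size=2, p=p)
    return calls


def _mate(rng: np.random.Generator, mother: np.ndarray, father: np.ndarray) -> np.ndarray:
    L = mother.shape[0]
    idx_m = rng.integers(2, size=L)
    idx_f = rng.integers(2, size=L)
    return np.stack([mother[np.arange(L), idx_m], father[np.arange(L), idx_f]], axis=1)


def _corrupt(
    rng: np.random.Generator,
    calls: np.ndarray,
    freqs: AlleleFrequencies,
    mistype_rate: float,
    prop_typed: float,
) -> np.ndarray:
    out = calls.copy()
    L = out.shape[0]
    for l in range(L):
        if rng.random() > prop_typed:
            out[l] = (MISSING, MISSING)
            continue
        if rng.random() < mistype_rate:
            alleles = np.array(list(freqs.freqs[l]))
            p = np.array(list(freqs.freqs[l].values()))
            out[l, rng.integers(2)] = rng.choice(alleles, p=p)
    return out


def _critical_from_deltas(deltas: np.ndarray, correct: np.ndarray, level: float) -> tuple[float, float]:
    """Smallest Delta threshold at which the assignments above it reach `level` accuracy.

    Returns (critical delta, fraction of offspring assigned at that threshold).
    """
    order = np.argsort(-deltas)
    d_sorted = deltas[order]
    c_sorted = correct[order]
    cum_correct = np.cumsum(c_sorted)
    n = np.arange(1, len(d_sorted) + 1)
    rate = cum_correct / n
    ok = np.flatnonzero(rate >= level)
    if ok.size == 0:
        raise ValueError(f"no Delta threshold reaches {level:.0%} accuracy in the simulation")
    best = ok.max()  # largest accepted set still meeting the level
    crit = float(d_sorted[best])
    return crit, (best + 1) / len(d_sorted)


def simulate_confidence(
    pop_freqs: AlleleFrequencies,
    n_offspring: int = 10_000,
    prop_parents_sampled: float = 0.5,
    n_candidates: int = 40,
    error: float = DEFAULT_ERROR,
    mistype_rate: float = 0.01,
    prop_loci_typed: float = 1.0,
    min_loci: int = DEFAULT_MIN_LOCI,
    seed: int | None = None,
) -> CriticalDeltas:
    """Simulate mating events to calibrate critical Delta values.

    Each simulated offspring is produced by two random parents drawn from
    the population allele frequencies; with probability
    ``prop_parents_sampled`` one true parent is placed in the candidate
    set (of size ``n_candidates``, the rest unrelated).  Genotypes are
    corrupted at ``mistype_rate`` per locus and thinned to
    ``prop_loci_typed``.  The critical Delta at each confidence level is
    the smallest Delta above which the realized accuracy of best-candidate
    assignments is at least that level.
    """
    rng = np.random.default_rng(seed)
    deltas = np.zeros(n_offspring)
    correct = np.zeros(n_offspring, dtype=bool)
    for s in range(n_offspring):
        mother = _sample_genotype(rng, pop_freqs)
        father = _sample_genotype(rng, pop_freqs)
        off = _mate(rng, mother, father)
        candidates = [_sample_genotype(rng, pop_freqs) for _ in range(n_candidates - 1)]
        sampled = rng.random() < prop_parents_sampled
        true_idx = -1
        if sampled:
            true_idx = int(rng.integers(n_candidates))
            candidates.insert(true_idx, mother)
        else:
            candidates.append(_sample_genotype(rng, pop_freqs))
        off_obs = _corrupt(rng, off, pop_freqs, mistype_rate, prop_loci_typed)
        lods = np.array(
            [
                lod_single_parent(off_obs, c, pop_freqs, error=error, min_loci=min_loci)[0]
                for c in candidates
            ]
        )
        best = int(np.argmax(lods))
        second = np.partition(lods, -2)[-2] if len(lods) > 1 else -math.inf
        best_lod = lods[best]
        deltas[s] = best_lod - second if math.isfinite(best_lod) else 0.0
        correct[s] = sampled and best == true_idx
    if not correct.any():
        raise ValueError("no correct assignments in simulation; confidence undefined")
    d95, rate95 = _critical_from_deltas(deltas, correct, 0.95)
    d80, rate80 = _critical_from_deltas(deltas, correct, 0.80)
    return CriticalDeltas(d95, d80, rate95, rate80, n_offspring)


@dataclass
class ParentageAssignment:
    offspring: str
    candidate: str | None
    lod: float
    delta: float
    confidence: str  # strict95 | relaxed80 | none
    mismatches: int


@dataclass
class DispersalSummary:
    distances: dict[str, list[float]]  # stand -> parent-offspring distances (m)

    def minmax(self) -> dict[str, tuple[float, float]]:
        return {s: (min(d), max(d)) for s, d in self.distances.items() if d}


class ParentageModel:
    """Parentage of a regeneration cohort against the stand's adults."""

    def __init__(
        self,
        offspring: GenotypeTable,
        candidates: GenotypeTable,
        pop_freqs: AlleleFrequencies | None = None,
        error: float = DEFAULT_ERROR,
        min_loci: int = DEFAULT_MIN_LOCI,
    ):
        self.offspring = offspring
        self.candidates = candidates
        # allele frequencies of the mating population default to adults+offspring
        from .genotypes import concat_tables

        self.pop_freqs = (
            pop_freqs
            if pop_freqs is not None
            else concat_tables([candidates, offspring]).allele_frequencies()
        )
        self.error = error
        self.min_loci = min_loci

    def simulate_confidence(self, **kwargs) -> CriticalDeltas:
        kwargs.setdefault("n_candidates", len(self.candidates))
        kwargs.setdefault("error", self.error)
        kwargs.setdefault("min_loci", self.min_loci)
        return simulate_confidence(self.pop_freqs, **kwargs)

    def fit(self, critical: CriticalDeltas) -> "ParentageResults":
        assignments = []
        for i, oid in enumerate(self.offspring.individuals):
            lods, mism = [], []
            for j in range(len(self.candidates)):
                try:
                    lod, _, mm = lod_single_parent(
                        self.offspring.calls[i],
                        self.candidates.calls[j],
                        self.pop_freqs,
                        error=self.error,
                        min_loci=self.min_loci,
                    )
                except ValueError:
                    lod, mm = -math.inf, -1
                lods.append(lod)
                mism.append(mm)
            lods_arr = np.array(lods)
            best = int(np.argmax(lods_arr))
            best_lod = lods_arr[best]
            if not math.isfinite(best_lod):
                assignments.append(
                    ParentageAssignment(oid, None, -math.inf, 0.0, "none", 0)
                )
                continue
            second = np.partition(lods_arr, -2)[-2] if len(lods_arr) > 1 else -math.inf
            delta = best_lod - second if math.isfinite(second) else math.inf
            if delta >= critical.strict95:
                conf = "strict95"
            elif delta >= critical.relaxed80:
                conf = "relaxed80"
            else:
                conf = "none"
            assignments.append(
                ParentageAssignment(
                    oid, self.candidates.individuals[best], float(best_lod), float(delta), conf, mism[best]
                )
            )
        return ParentageResults(assignments, critical)


@dataclass
class ParentageResults:
    assignments: list[ParentageAssignment]
    critical: CriticalDeltas

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offspring": [a.offspring for a in self.assignments],
                "candidate": [a.candidate for a in self.assignments],
                "LOD": [a.lod for a in self.assignments],
                "Delta": [a.delta for a in self.assignments],
                "confidence": [a.confidence for a in self.assignments],
                "mismatches": [a.mismatches for a in self.assignments],
            }
        ).set_index("offspring")

    def strict(self) -> list[ParentageAssignment]:
        return [a for a in self.assignments if a.confidence == "strict95"]

    def relaxed(self) -> list[ParentageAssignment]:
        return [a for a in self.assignments if a.confidence in ("strict95", "relaxed80")]

    def summary(self) -> str:
        df = self.frame()
        lines = ["Single-parent likelihood parentage", "-" * 36]
        lines.append(f"offspring analysed  : {len(df)}")
        lines.append(f"critical Delta 95%  : {self.critical.strict95:.3f}")
        lines.append(f"critical Delta 80%  : {self.critical.relaxed80:.3f}")
        counts = df["confidence"].value_counts()
        for c in ("strict95", "relaxed80", "none"):
            lines.append(f"  {c:10s}: {int(counts.get(c, 0))}")
        return "\n".join(lines)


def dispersal_distances(
    results: ParentageResults,
    coords: CoordinateSet,
    stand_of: dict[str, str] | None = None,
    strict_only: bool = True,
) -> DispersalSummary:
    """Euclidean parent-offspring distances for assigned pairs.

    Pairs with a missing coordinate are skipped.  ``stand_of`` maps
    offspring ids to stand names (one pooled stand when omitted).
    """
    pairs = results.strict() if strict_only else results.relaxed()
    distances: dict[str, list[float]] = {}
    for a in pairs:
        if a.candidate is None:
            continue
        if a.offspring not in coords or a.candidate not in coords:
            continue
        d = float(np.linalg.norm(coords.get(a.offspring) - coords.get(a.candidate)))
        stand = stand_of.get(a.offspring, "stand") if stand_of else "stand"
        distances.setdefault(stand, []).append(d)
    return DispersalSummary(distances)
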