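"""Varietal admixture estimation and population assignment.

Two layers mirror a hierarchical origin analysis for individuals of
unknown provenance scored at codominant SSR loci:

* a supervised maximum-likelihood admixture estimator: given fixed allele
  frequencies of two reference gene pools, each individual's membership
  coefficient Qvar to pool A is estimated by EM on the mixture likelihood
  of its allele copies, and classified coastal / interior / hybrid by the
  0.8 / 0.2 thresholds (the thresholds themselves can be recalibrated with
  simulated F1 genotypes);
* per-reference-population assignment likelihoods: the frequency-based
  measure (genotype likelihood under reference frequencies with a floor
  for unobserved alleles) and the Bayesian measure (posterior-predictive
  genotype probability under a uniform 1/k Dirichlet prior on reference
  allele counts), both reported as percentage scores across references.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, AlleleFrequencies, GenotypeTable

HYBRID_LOW = 0.2
HYBRID_HIGH = 0.8
DEFAULT_FREQ_FLOOR = 0.01
DEFAULT_MIN_LOCI = 9


def classify_variety(q: float, low: float = HYBRID_LOW, high: float = HYBRID_HIGH) -> str:
    """Threshold a membership coefficient into coastal / interior / hybrid.

    The parental classes use strict inequalities, so boundary values land
    in the hybrid class.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("Qvar must lie in [0, 1]")
    if q > high:
        return "coastal"
    if q < low:
        return "interior"
    return "hybrid"


def _floored(freqs: dict[int, float], alleles: tuple[int, ...] | list[int], floor: float) -> dict[int, float]:
    """Floor zero frequencies at `floor` and renormalize over `alleles`."""
    raw = {a: max(freqs.get(a, 0.0), floor) for a in alleles}
    tot = sum(raw.values())
    return {a: v / tot for a, v in raw.items()}


@dataclass
class QEstimate:
    individual: str
    q: float
    loglik: float
    n_loci: int
    n_iter: int

    @property
    def variety(self) -> str:
        return classify_variety(self.q)


def supervised_q(
    calls: np.ndarray,
    freq_a: AlleleFrequencies,
    freq_b: AlleleFrequencies,
    floor: float = DEFAULT_FREQ_FLOOR,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[float, float, int]:
    """EM estimate of the membership coefficient q of one individual.

    ``calls`` is the (L, 2) allele-pair array of the individual.  The
    mixture likelihood treats each non-missing allele copy independently:
    L(q) = prod over copies of [q * pA + (1-q) * pB].  Zero reference
    frequencies are floored (and renormalized) so every observed allele
    has support under both pools.  Returns (q, log-likelihood, n_iter);
    a completely uninformative likelihood stays at the symmetric start 0.5.
    """
    pa, pb = [], []
    for l in range(calls.shape[0]):
        a1, a2 = calls[l]
        if a1 == MISSING:
            continue
        alleles = sorted(set(freq_a.freqs[l]) | set(freq_b.freqs[l]) | {int(a1), int(a2)})
        fa = _floored(freq_a.freqs[l], alleles, floor)
        fb = _floored(freq_b.freqs[l], alleles, floor)
        for a in (a1, a2):
            pa.append(fa[int(a)])
            pb.append(fb[int(a)])
    pa_arr, pb_arr = np.array(pa), np.array(pb)
    if pa_arr.size == 0:
        raise ValueError("individual has no genotyped loci")
    q = 0.5
    ll_prev = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        mix = q * pa_arr + (1 - q) * pb_arr
        ll = float(np.sum(np.log(mix)))
        if ll + 1e-12 < ll_prev:  # EM guarantees monotone likelihood
            raise RuntimeError("EM likelihood decreased")
        q_new = float(np.mean(q * pa_arr / mix))
        converged = abs(q_new - q) < tol
        q, ll_prev = q_new, ll
        if converged:
            break
    q = min(max(q, 0.0), 1.0)
    mix = q * pa_arr + (1 - q) * pb_arr
    return q, float(np.sum(np.log(mix))), it


@dataclass
class AdmixtureResults:
    """Per-individual membership coefficients with varietal classes."""

    estimates: list[QEstimate]
    excluded: list[str] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual": [e.individual for e in self.estimates],
                "Qvar": [e.q for e in self.estimates],
                "class": [e.variety for e in self.estimates],
                "loglik": [e.loglik for e in self.estimates],
                "n_loci": [e.n_loci for e in self.estimates],
            }
        ).set_index("individual")

    def summary(self) -> str:
        df = self.frame()
        counts = df["class"].value_counts()
        lines = ["Supervised admixture (Qvar to pool A)", "-" * 38]
        lines.append(f"individuals scored : {len(df)}")
        lines.append(f"excluded (<min loci): {len(self.excluded)}")
        for cls in ("coastal", "hybrid", "interior"):
            lines.append(f"  {cls:9s}: {int(counts.get(cls, 0))}")
        lines.append(f"mean Qvar          : {df['Qvar'].mean():.3f}")
        return "\n".join(lines)


class AdmixtureModel:
    """Supervised two-pool admixture model for a query table.

    Reference pools are fixed and labelled (varieties or clusters); the
    model estimates, per query individual, the proportion of its genome
    drawn from pool A.
    """

    def __init__(
        self,
        query: GenotypeTable,
        freq_a: AlleleFrequencies,
        freq_b: AlleleFrequencies,
        floor: float = DEFAULT_FREQ_FLOOR,
        min_loci: int = DEFAULT_MIN_LOCI,
    ):
        if [l.name for l in query.loci] != [l.name for l in freq_a.loci] or [
            l.name for l in query.loci
        ] != [l.name for l in freq_b.loci]:
            raise ValueError("query and reference frequencies must share loci")
        self.query = query
        self.freq_a = freq_a
        self.freq_b = freq_b
        self.floor = floor
        self.min_loci = min_loci

    def fit(self, tol: float = 1e-6, max_iter: int = 1000) -> AdmixtureResults:
        typed = self.query.n_typed()
        estimates, excluded = [], []
        for i, ind in enumerate(self.query.individuals):
            if typed[i] < self.min_loci:
                excluded.append(ind)
                continue
            q, ll, it = supervised_q(
                self.query.calls[i], self.freq_a, self.freq_b, self.floor, tol, max_iter
            )
            estimates.append(QEstimate(ind, q, ll, int(typed[i]), it))
        return AdmixtureResults(estimates, excluded)


# ---------------------------------------------------------------------- #
# F1 simulation and threshold calibration
# ---------------------------------------------------------------------- #


def simulate_f1(
    pool_a: GenotypeTable,
    pool_b: GenotypeTable,
    n_f1: int = 120,
    seed: int | None = None,
    prefix: str = "F1",
) -> GenotypeTable:
    """Simulate F1 crosses between two parental pools.

    Each F1 receives, per locus, one allele drawn from pool A's observed
    allele-frequency distribution and one from pool B's (the gamete-pool
    convention of hybrid-simulation software).
    """
    if len(pool_a) == 0 or len(pool_b) == 0:
        raise ValueError("parental pools must be non-empty")
    fa = pool_a.allele_frequencies()
    fb = pool_b.allele_frequencies()
    rng = np.random.default_rng(seed)
    L = pool_a.n_loci
    calls = np.zeros((n_f1, L, 2), dtype=int)
    for l in range(L):
        if not fa.freqs[l] or not fb.freqs[l]:
            raise ValueError(f"locus {pool_a.loci[l].name!r} has no data in a pool")
        a_alleles = np.array(list(fa.freqs[l]))
        a_p = np.array(list(fa.freqs[l].values()))
        b_alleles = np.array(list(fb.freqs[l]))
        b_p = np.array(list(fb.freqs[l].values()))
        calls[:, l, 0] = rng.choice(a_alleles, size=n_f1, p=a_p)
        calls[:, l, 1] = rng.choice(b_alleles, size=n_f1, p=b_p)
    return GenotypeTable.from_calls(
        [f"{prefix}-{k+1:03d}" for k in range(n_f1)],
        [l.name for l in pool_a.loci],
        calls,
        [prefix] * n_f1,
    )


def calibrate_thresholds(
    parental_a: GenotypeTable,
    parental_b: GenotypeTable,
    n_f1: int = 120,
    replicates: int = 5,
    seed: int | None = None,
    floor: float = DEFAULT_FREQ_FLOOR,
) -> pd.DataFrame:
    """Confusion table of the 0.8/0.2 hybrid thresholds on simulated data.

    Per replicate, ``n_f1`` F1 genotypes are simulated between the two
    parental pools; parental and F1 individuals are scored with the
    supervised admixture estimator against the pools' own frequencies and
    cross-tabulated against their true class.  Returns one row per
    (replicate, true class) plus a pooled block (replicate = "pooled").
    """
    freq_a = parental_a.allele_frequencies()
    freq_b = parental_b.allele_frequencies()
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, replicates + 1):
        f1 = simulate_f1(parental_a, parental_b, n_f1, seed=int(rng.integers(2**31)))
        for true_class, tab in (
            ("coastal", parental_a),
            ("interior", parental_b),
            ("hybrid", f1),
        ):
            res = AdmixtureModel(tab, freq_a, freq_b, floor=floor, min_loci=1).fit()
            counts = res.frame()["class"].value_counts()
            rows.append(
                {
                    "replicate": rep,
                    "true_class": true_class,
                    "n": len(res.estimates),
                    "coastal": int(counts.get("coastal", 0)),
                    "hybrid": int(counts.get("hybrid", 0)),
                    "interior": int(counts.get("interior", 0)),
                }
            )
    df = pd.DataFrame(rows)
    pooled = (
        df.groupby("true_class", sort=False)[["n", "coastal", "hybrid", "interior"]]
        .sum()
        .reset_index()
    )
    pooled.insert(0, "replicate", "pooled")
    return pd.concat([df, pooled], ignore_index=True)


# ---------------------------------------------------------------------- #
# Per-reference assignment likelihoods
# ---------------------------------------------------------------------- #


def paetkau_loglik(
    calls: np.ndarray, ref: AlleleFrequencies, floor: float = DEFAULT_FREQ_FLOOR
) -> float:
    """Frequency-based assignment log-likelihood of one individual.

    Sum over non-missing loci of the log HWE genotype probability under
    the reference allele frequencies; alleles unobserved in the reference
    are given the floor frequency (frequencies renormalized), keeping the
    log-likelihood finite.
    """
    ll = 0.0
    for l in range(calls.shape[0]):
        a1, a2 = int(calls[l, 0]), int(calls[l, 1])
        if a1 == MISSING:
            continue
        alleles = sorted(set(ref.freqs[l]) | {a1, a2})
        f = _floored(ref.freqs[l], alleles, floor)
        ll += math.log(f[a1] ** 2 if a1 == a2 else 2 * f[a1] * f[a2])
    return ll


def rannala_mountain_loglik(
    calls: np.ndarray, ref_counts: list[dict[int, float]], k_per_locus: list[int]
) -> float:
    """Bayesian assignment log-likelihood of one individual.

    Posterior-predictive genotype probability under a symmetric Dirichlet
    (1/k per allele) prior on the reference allele counts, with k the
    number of alleles observed at the locus across all references:
    hom aa -> (n_a + 1/k)(n_a + 1 + 1/k) / ((n + 1)(n + 2));
    het ab -> 2 (n_a + 1/k)(n_b + 1/k) / ((n + 1)(n + 2)).
    """
    ll = 0.0
    for l in range(calls.shape[0]):
        a1, a2 = int(calls[l, 0]), int(calls[l, 1])
        if a1 == MISSING:
            continue
        counts = ref_counts[l]
        k = k_per_locus[l]
        n = sum(counts.values())
        na = counts.get(a1, 0.0)
        if a1 == a2:
            p = (na + 1.0 / k) * (na + 1.0 + 1.0 / k) / ((n + 1.0) * (n + 2.0))
        else:
            nb = counts.get(a2, 0.0)
            p = 2.0 * (na + 1.0 / k) * (nb + 1.0 / k) / ((n + 1.0) * (n + 2.0))
        ll += math.log(p)
    return ll


@dataclass
class AssignmentResults:
    """Per-individual percentage scores across reference populations."""

    scores: pd.DataFrame  # individuals x references, rows sum to 100
    logliks: pd.DataFrame
    measure: str
    group_of: dict[str, str]

    def population_summary(self) -> pd.DataFrame:
        """Mean % score per (query population, reference); best reference first."""
        df = self.scores.copy()
        df["population"] = [self.group_of[i] for i in df.index]
        mean = df.groupby("population", sort=False).mean()
        best = mean.idxmax(axis=1)
        ties = (mean.eq(mean.max(axis=1), axis=0)).sum(axis=1)
        out = mean.copy()
        out.insert(0, "assigned", best)
        out.insert(1, "tied", ties > 1)
        return out

    def summary(self) -> str:
        pop = self.population_summary()
        lines = [f"Population assignment ({self.measure} measure)", "-" * 44]
        for p, row in pop.iterrows():
            flag = " (tie)" if row["tied"] else ""
            lines.append(
                f"{p:12s} -> {row['assigned']:8s} "
                f"(mean score {row[row['assigned']]:.1f}%){flag}"
            )
        return "\n".join(lines)


def assign(
    query: GenotypeTable,
    references: GenotypeTable,
    measure: str = "rannala",
    floor: float = DEFAULT_FREQ_FLOOR,
    min_loci: int = DEFAULT_MIN_LOCI,
) -> AssignmentResults:
    """Score each query individual against every reference population.

    Log-likelihoods per reference are converted to percentage scores
    L_r / sum_r L_r (on the likelihood scale, per individual).  The
    population-level assignment is the reference maximizing the mean
    percentage score over a query population's individuals.
    """
    if measure not in ("paetkau", "rannala"):
        raise ValueError("measure must be 'paetkau' or 'rannala'")
    refs = references.group_names
    if len(refs) < 2:
        raise ValueError("need at least 2 reference populations")
    ref_freqs = {r: references.allele_frequencies(r) for r in refs}
    if measure == "rannala":
        k_per_locus = []
        all_freqs = references.allele_frequencies()
        for l in range(references.n_loci):
            k_per_locus.append(max(len(all_freqs.freqs[l]), 1))
        ref_counts = {r: [ref_freqs[r].counts(l) for l in range(references.n_loci)] for r in refs}
    typed = query.n_typed()
    rows, kept = [], []
    for i, ind in enumerate(query.individuals):
        if typed[i] < min_loci:
            continue
        kept.append(ind)
        if measure == "paetkau":
            lls = [paetkau_loglik(query.calls[i], ref_freqs[r], floor) for r in refs]
        else:
            lls = [
                rannala_mountain_loglik(query.calls[i], ref_counts[r], k_per_locus) for r in refs
            ]
        rows.append(lls)
    ll = pd.DataFrame(rows, index=kept, columns=refs)
    shifted = ll.sub(ll.max(axis=1), axis=0)
    lik = np.exp(shifted)
    scores = lik.div(lik.sum(axis=1), axis=0) * 100.0
    group_of = {ind: query.groups[query.index_of(ind)] for ind in kept}
    return AssignmentResults(scores, ll, measure, group_of)
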