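"""Founder-effect tests for introduced populations.

Three complementary procedures probe whether introduced stands lost
genetic diversity relative to the native range:

* a subsampling t-test battery: many random same-sized groups of native
  populations are compared to the introduced populations by pooled
  two-sample t-tests on a diversity index (He or rarefied allelic
  richness), with a Shapiro-Wilk normality check per draw;
* a heterozygote-excess bottleneck test: for each locus the observed gene
  diversity is compared to the distribution expected at mutation-drift
  equilibrium for the observed number of alleles and sample size, obtained
  by coalescent simulation under IAM, SMM or the two-phase mutation model
  (TPM); a one-tailed Wilcoxon signed-rank test combines loci;
* the allele-frequency mode-shift indicator: a population at equilibrium
  shows an L-shaped allele-frequency class distribution, which a recent
  bottleneck distorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeTable
from .diversity import diversity_summary

DEFAULT_P_SMM = 0.7
DEFAULT_VAR_GEOM = 0.30


# ---------------------------------------------------------------------- #
# Subsample t-test battery
# ---------------------------------------------------------------------- #


def european_split_means(
    table: GenotypeTable,
    groups: list[str],
    index: str = "uhe",
    half_size: int = 20,
    g_copies: int = 20,
    seed: int | None = None,
) -> dict[str, float]:
    """Mean diversity index over two random disjoint halves per population.

    Each population is split into two disjoint random halves of
    ``half_size`` individuals, the index is computed per half and the two
    values averaged; this balances the larger introduced samples against
    native reference samples.  Populations with fewer than 2*half_size
    individuals are used whole with a warning.  ``index`` is an attribute
    of :class:`~seedsource.diversity.DiversitySummary` ("uhe", "he",
    "as_g", ...).
    """
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}
    for g in groups:
        sub = table.subset(group=g)
        n = len(sub)
        if n < 2 * half_size:
            warnings.warn(f"population {g}: only {n} individuals, used whole")
            out[g] = float(getattr(diversity_summary(sub, g_copies=g_copies), index))
            continue
        perm = rng.permutation(n)
        halves = [perm[:half_size], perm[half_size : 2 * half_size]]
        vals = [
            getattr(diversity_summary(sub.subset(indices=h), g_copies=g_copies), index)
            for h in halves
        ]
        out[g] = float(np.mean(vals))
    return out


@dataclass
class SubsampleComparison:
    """Result of the t-test battery of one diversity index."""

    index: str
    eu_values: np.ndarray
    n_groups: int
    group_size: int
    alpha: float
    t_stats: np.ndarray
    p_values: np.ndarray
    shapiro_p: np.ndarray
    df: int

    @property
    def fraction_significant(self) -> float:
        return float(np.mean(self.p_values < self.alpha))

    @property
    def fraction_non_normal(self) -> float:
        return float(np.mean(self.shapiro_p < self.alpha))

    def summary(self) -> str:
        return (
            f"{self.index}: {self.n_groups} pooled t-tests (df={self.df}), "
            f"{self.fraction_significant:.1%} significant at alpha={self.alpha}; "
            f"{self.fraction_non_normal:.1%} of draws non-normal (Shapiro-Wilk)"
        )


def pooled_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Two-sample pooled-variance t-test; returns (t, df, two-sided p).

    The sign convention is mean(a) - mean(b).
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), len(a) + len(b) - 2, float(p)


def subsample_ttest_battery(
    eu_values,
    na_values,
    n_groups: int = 1000,
    group_size: int = 6,
    alpha: float = 0.05,
    seed: int | None = None,
    index: str = "index",
) -> SubsampleComparison:
    """Pooled t-tests of the introduced values against random native groups.

    Each of ``n_groups`` draws takes ``group_size`` native values without
    replacement (within the draw), checks normality with Shapiro-Wilk, and
    runs a pooled two-sample t-test against the introduced values (sign
    convention: introduced minus native).
    """
    eu = np.asarray(eu_values, float)
    na = np.asarray(na_values, float)
    if group_size > na.size:
        raise ValueError(f"group_size {group_size} exceeds {na.size} native values")
    rng = np.random.default_rng(seed)
    t_stats = np.zeros(n_groups)
    p_values = np.zeros(n_groups)
    shapiro_p = np.zeros(n_groups)
    df = eu.size + group_size - 2
    for g in range(n_groups):
        draw = na[rng.choice(na.size, size=group_size, replace=False)]
        if np.ptp(draw) == 0:
            shapiro_p[g] = np.nan
        else:
            shapiro_p[g] = stats.shapiro(draw).pvalue
        if np.ptp(draw) == 0 and np.ptp(eu) == 0 and draw[0] == eu[0]:
            t_stats[g], p_values[g] = 0.0, 1.0
        else:
            t_stats[g], _, p_values[g] = pooled_ttest(eu, draw)
    return SubsampleComparison(
        index, eu, n_groups, group_size, alpha, t_stats, p_values, shapiro_p, df
    )


# ---------------------------------------------------------------------- #
# Coalescent simulation of equilibrium gene diversity (Heq)
# ---------------------------------------------------------------------- #


def _geom_q(var_geom: float) -> float:
    # geometric on {1, 2, ...} with variance (1-q)/q^2 = var_geom
    if var_geom <= 0:
        return 1.0
    return (-1.0 + np.sqrt(1.0 + 4.0 * var_geom)) / (2.0 * var_geom)


def _simulate_locus(
    rng: np.random.Generator,
    n: int,
    theta: float,
    model: str,
    p_smm: float,
    q_geom: float,
) -> np.ndarray:
    """One coalescent replicate; returns the n sampled allele states.

    Working backward from the present, mutations hit each extant lineage
    at rate theta/2.  Under IAM a leaf's allele is the label of the most
    recent mutation on its path (the first met going backward); under the
    stepwise models the allele is the cumulative step sum along the path.
    """
    lin_id = np.arange(n)  # lineage membership per leaf
    state = np.zeros(n, dtype=np.int64)  # cumulative steps (stepwise)
    iam = np.full(n, -1, dtype=np.int64)  # most-recent-mutation label
    next_label = 1
    k = n
    stepwise = model != "iam"
    while k > 1:
        t = rng.exponential(2.0 / (k * (k - 1)))
        n_mut = rng.poisson(0.5 * theta * t * k)
        if n_mut:
            hit = rng.integers(k, size=n_mut)
            if stepwise:
                if model == "smm":
                    steps = np.ones(n_mut, dtype=np.int64)
                else:
                    multi = rng.random(n_mut) >= p_smm
                    steps = np.ones(n_mut, dtype=np.int64)
                    if multi.any():
                        steps[multi] += rng.geometric(q_geom, size=int(multi.sum()))
                steps[rng.random(n_mut) < 0.5] *= -1
                per_lin = np.zeros(k, dtype=np.int64)
                np.add.at(per_lin, hit, steps)
                state += per_lin[lin_id]
            else:
                for j in np.unique(hit):
                    mask = (lin_id == j) & (iam < 0)
                    iam[mask] = next_label
                    next_label += 1
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        lin_id[lin_id == j] = i
        lin_id[lin_id == k - 1] = j if j != k - 1 else i  # keep ids dense
        k -= 1
    if model == "iam":
        return np.where(iam < 0, 0, iam)
    return state


def _mean_allele_count(
    rng: np.random.Generator, n: int, theta: float, model: str, p_smm: float, q_geom: float, n_eval: int
) -> float:
    ks = [
        np.unique(_simulate_locus(rng, n, theta, model, p_smm, q_geom)).size
        for _ in range(n_eval)
    ]
    return float(np.mean(ks))


def tune_theta(
    n: int,
    k: int,
    model: str = "tpm",
    p_smm: float = DEFAULT_P_SMM,
    var_geom: float = DEFAULT_VAR_GEOM,
    n_eval: int = 120,
    n_iter: int = 12,
    seed: int | None = None,
    max_theta: float = 64000.0,
) -> float:
    """Bisection on theta so the mean simulated allele count matches k."""
    rng = np.random.default_rng(seed)
    q_geom = _geom_q(var_geom)
    lo, hi = 1e-3, min(8.0, max_theta)
    k_lo = _mean_allele_count(rng, n, lo, model, p_smm, q_geom, max(30, n_eval // 4))
    if k < k_lo:
        raise ValueError(
            f"cannot bracket k={k} for n={n} copies under {model}: "
            f"mean allele count is {k_lo:.2f} already at theta={lo}"
        )
    while (
        _mean_allele_count(rng, n, hi, model, p_smm, q_geom, max(30, n_eval // 4)) < k
    ):
        if hi >= max_theta:
            raise ValueError(
                f"cannot bracket k={k} for n={n} copies under {model}: "
                f"mean allele count still below k at theta={hi:.0f}"
            )
        hi = min(hi * 4.0, max_theta)
    for _ in range(n_iter):
        mid = np.sqrt(lo * hi)
        k_mid = _mean_allele_count(rng, n, mid, model, p_smm, q_geom, n_eval)
        if k_mid < k:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def _unbiased_he(states: np.ndarray) -> float:
    n = states.size
    _, counts = np.unique(states, return_counts=True)
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def simulate_heq(
    n: int,
    k: int,
    model: str = "tpm",
    n_sim: int = 1000,
    p_smm: float = DEFAULT_P_SMM,
    var_geom: float = DEFAULT_VAR_GEOM,
    seed: int | None = None,
    max_attempts_factor: int = 200,
    theta: float | None = None,
) -> np.ndarray:
    """Equilibrium gene-diversity (Heq) sample conditional on k alleles.

    Coalescent replicates of ``n`` gene copies are simulated at a mutation
    rate tuned so the mean allele count matches ``k``; replicates with
    exactly k alleles are retained (the standard conditioning of
    equilibrium bottleneck tests) and their unbiased gene diversities
    returned.
    """
    if not 2 <= k <= n:
        raise ValueError("need 2 <= k <= n (monomorphic loci are excluded upstream)")
    if model not in ("iam", "smm", "tpm"):
        raise ValueError("model must be 'iam', 'smm' or 'tpm'")
    rng = np.random.default_rng(seed)
    if theta is None:
        theta = tune_theta(
            n, k, model, p_smm, var_geom, seed=int(rng.integers(2**31))
        )
    q_geom = _geom_q(var_geom)
    out = []
    attempts = 0
    max_attempts = max_attempts_factor * n_sim
    while len(out) < n_sim and attempts < max_attempts:
        attempts += 1
        states = _simulate_locus(rng, n, theta, model, p_smm, q_geom)
        if np.unique(states).size == k:
            out.append(_unbiased_he(states))
    if len(out) < n_sim:
        raise ValueError(
            f"only {len(out)}/{n_sim} replicates hit k={k} alleles in "
            f"{max_attempts} attempts (n={n}, theta={theta:.3g}, {model})"
        )
    return np.array(out)


# ---------------------------------------------------------------------- #
# Bottleneck test and mode-shift indicator
# ---------------------------------------------------------------------- #

MODE_SHIFT_EDGES = np.arange(0.0, 1.01, 0.1)


def mode_shift(frequencies) -> tuple[np.ndarray, bool]:
    """Allele-frequency class histogram and L-shape verdict.

    Frequencies are pooled over loci into ten right-closed classes
    (0, 0.1], (0.1, 0.2], ...; the distribution is L-shaped iff the lowest
    class holds strictly more alleles than every other class.
    """
    freqs = np.asarray(list(frequencies), float)
    idx = np.clip(np.ceil(freqs * 10.0 - 1e-12).astype(int) - 1, 0, 9)
    hist = np.bincount(idx, minlength=10)
    l_shaped = bool(np.all(hist[0] > hist[1:]))
    return hist, l_shaped


@dataclass
class BottleneckResult:
    """Per-locus equilibrium comparison plus the combined tests."""

    group: str
    model: str
    per_locus: pd.DataFrame  # he_obs, heq_mean, heq_sd, std_diff, n, k
    wilcoxon_p_excess: float
    mode_shift_hist: np.ndarray
    l_shaped: bool
    skipped_loci: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [f"Bottleneck test: {self.group} ({self.model.upper()})", "-" * 40]
        lines.append(self.per_locus.to_string(float_format=lambda v: f"{v:.4f}"))
        lines.append(f"one-tailed Wilcoxon p (heterozygote excess): {self.wilcoxon_p_excess:.4f}")
        lines.append(f"allele-frequency classes: {self.mode_shift_hist.tolist()}")
        lines.append(f"L-shaped distribution: {self.l_shaped}")
        return "\n".join(lines)


def bottleneck_test(
    table: GenotypeTable,
    group: str | None = None,
    model: str = "tpm",
    n_sim: int = 1000,
    p_smm: float = DEFAULT_P_SMM,
    var_geom: float = DEFAULT_VAR_GEOM,
    seed: int | None = None,
) -> BottleneckResult:
    """Heterozygote-excess bottleneck test of one population.

    For every polymorphic locus the observed unbiased gene diversity is
    compared to the simulated equilibrium distribution conditional on the
    observed allele count; the one-tailed Wilcoxon signed-rank test on the
    per-locus differences asks for a systematic excess, the signature of a
    recent bottleneck.
    """
    sub = table if group is None else table.subset(group=group)
    freqs = sub.allele_frequencies()
    rng = np.random.default_rng(seed)
    rows, skipped, pooled_freqs = [], [], []
    theta_cache: dict[tuple[int, int], float] = {}
    for l, locus in enumerate(sub.loci):
        f = freqs.freqs[l]
        n = int(freqs.copies[l])
        k = len(f)
        if k < 2 or n < 4:
            skipped.append(locus.name)
            continue
        pooled_freqs.extend(f.values())
        col = sub.calls[:, l, :]
        states = col[col[:, 0] != MISSING].ravel()
        he_obs = _unbiased_he(states)
        if (n, k) not in theta_cache:
            theta_cache[(n, k)] = tune_theta(
                n, k, model, p_smm, var_geom, seed=int(rng.integers(2**31))
            )
        heq = simulate_heq(
            n, k, model, n_sim, p_smm, var_geom,
            seed=int(rng.integers(2**31)), theta=theta_cache[(n, k)],
        )
        mu, sd = float(heq.mean()), float(heq.std(ddof=1))
        rows.append(
            {
                "locus": locus.name,
                "n": n,
                "k": k,
                "he_obs": he_obs,
                "heq_mean": mu,
                "heq_sd": sd,
                "std_diff": (he_obs - mu) / sd if sd > 0 else np.nan,
            }
        )
    if len(rows) < 4:
        raise ValueError("need >= 4 polymorphic loci for the Wilcoxon test")
    per_locus = pd.DataFrame(rows).set_index("locus")
    diffs = (per_locus["he_obs"] - per_locus["heq_mean"]).to_numpy()
    p_excess = float(stats.wilcoxon(diffs, alternative="greater").pvalue)
    hist, l_shaped = mode_shift(pooled_freqs)
    return BottleneckResult(
        group=group if group is not None else "(all)",
        model=model,
        per_locus=per_locus,
        wilcoxon_p_excess=p_excess,
        mode_shift_hist=hist,
        l_shaped=l_shaped,
        skipped_loci=skipped,
    )
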