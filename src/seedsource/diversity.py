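"""Per-population genetic diversity indices and Hardy-Weinberg testing.

Implements the standard codominant-marker summaries (mean alleles per
locus Na, observed heterozygosity Ho, expected heterozygosity He and its
unbiased version uHe, inbreeding coefficient Fis), allelic richness
standardized by hypergeometric rarefaction, and a seedable Monte-Carlo
exact test for heterozygote deficit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, AlleleFrequencies, GenotypeTable

DEFAULT_RAREFACTION_COPIES = 20  # 10 diploid individuals


@dataclass
class DiversitySummary:
    """Diversity indices for one population.

    Scalar attributes are means over (usable) loci; `per_locus` carries the
    locus-level components.  Fis is the weighted mean of per-locus
    (He_used - Ho)/He_used with weights He_used, monomorphic loci excluded.
    """

    group: str
    n_individuals: int
    na: float
    ho: float
    he: float
    uhe: float
    fis: float
    as_g: float
    g_copies: int
    per_locus: pd.DataFrame = field(repr=False)
    excluded_loci: list[str] = field(default_factory=list)


def allelic_richness(counts, g: int) -> float:
    """Expected number of distinct alleles in a random draw of g gene copies.

    ``counts`` are the per-allele gene-copy counts of the full sample of
    N = sum(counts) copies.  Uses the exact hypergeometric form
    E[A(g)] = sum_a [1 - C(N - N_a, g) / C(N, g)], with C(m, g) = 0 when
    m < g.
    """
    counts = [int(c) for c in counts if c > 0]
    n_total = sum(counts)
    if g < 1:
        raise ValueError("g must be >= 1")
    if g > n_total:
        raise ValueError(f"g = {g} exceeds the sample of {n_total} gene copies")
    denom = math.comb(n_total, g)
    return float(sum(1.0 - math.comb(n_total - c, g) / denom for c in counts))


def _locus_stats(table: GenotypeTable, freqs: AlleleFrequencies, l: int) -> dict:
    col = table.calls[:, l, :]
    typed = col[:, 0] != MISSING
    n_ind = int(typed.sum())
    n_copies = int(freqs.copies[l])
    p = np.array(list(freqs.freqs[l].values()))
    na = len(p)
    ho = float((col[typed, 0] != col[typed, 1]).mean()) if n_ind else np.nan
    he = float(1.0 - np.sum(p**2)) if na else np.nan
    uhe = he * n_copies / (n_copies - 1) if n_copies > 1 else np.nan
    return {"n_ind": n_ind, "n_copies": n_copies, "na": na, "ho": ho, "he": he, "uhe": uhe}


def diversity_summary(
    table: GenotypeTable,
    group: str | None = None,
    g_copies: int = DEFAULT_RAREFACTION_COPIES,
    fis_on: str = "uhe",
) -> DiversitySummary:
    """Compute Na, Ho, He, uHe, Fis and rarefied allelic richness for a group.

    Parameters
    ----------
    fis_on : "uhe" (default) or "he" -- which gene-diversity estimate the
        per-locus Fis = (He_used - Ho)/He_used uses.  Per-locus values are
        combined with He_used weights; monomorphic loci contribute nothing.
    g_copies : rarefaction size in gene copies; loci (not populations) with
        fewer observed copies are excluded from the As mean and flagged.
    """
    sub = table if group is None else table.subset(group=group)
    if len(sub) < 2:
        raise ValueError("need at least 2 individuals")
    freqs = sub.allele_frequencies()
    rows, excluded = [], []
    for l, locus in enumerate(sub.loci):
        if not freqs.freqs[l]:
            excluded.append(locus.name)
            continue
        st = _locus_stats(sub, freqs, l)
        counts = [round(v) for v in freqs.counts(l).values()]
        st["as_g"] = (
            allelic_richness(counts, g_copies) if st["n_copies"] >= g_copies else np.nan
        )
        he_used = st["uhe"] if fis_on == "uhe" else st["he"]
        st["fis"] = (he_used - st["ho"]) / he_used if he_used and he_used > 0 else np.nan
        st["fis_weight"] = he_used if he_used and he_used > 0 else 0.0
        st["locus"] = locus.name
        rows.append(st)
    per_locus = pd.DataFrame(rows).set_index("locus")
    w = per_locus["fis_weight"].to_numpy()
    fis_vals = per_locus["fis"].to_numpy()
    ok = w > 0
    fis = float(np.sum(w[ok] * fis_vals[ok]) / np.sum(w[ok])) if ok.any() else np.nan
    return DiversitySummary(
        group=group if group is not None else "(all)",
        n_individuals=len(sub),
        na=float(per_locus["na"].mean()),
        ho=float(per_locus["ho"].mean()),
        he=float(per_locus["he"].mean()),
        uhe=float(per_locus["uhe"].mean()),
        fis=fis,
        as_g=float(per_locus["as_g"].mean(skipna=True)),
        g_copies=g_copies,
        per_locus=per_locus,
        excluded_loci=excluded,
    )


def summary_frame(
    table: GenotypeTable, g_copies: int = DEFAULT_RAREFACTION_COPIES
) -> pd.DataFrame:
    """One diversity row per population in the table."""
    rows = []
    for g in table.group_names:
        s = diversity_summary(table, g, g_copies=g_copies)
        rows.append(
            {
                "population": g,
                "n": s.n_individuals,
                "Na": s.na,
                "Ho": s.ho,
                "He": s.he,
                "uHe": s.uhe,
                "Fis": s.fis,
                f"As{g_copies // 2}": s.as_g,
            }
        )
    return pd.DataFrame(rows).set_index("population")


# ---------------------------------------------------------------------- #
# Hardy-Weinberg exact test (heterozygote deficit), Monte-Carlo
# ---------------------------------------------------------------------- #


def hwe_exact_test(
    table: GenotypeTable,
    group: str | None,
    locus: str,
    n_iter: int = 100_000,
    seed: int | None = None,
) -> float:
    """One-sided Monte-Carlo exact test for heterozygote deficit.

    Conditional on the observed allele counts, genotype tables are sampled
    by randomly re-pairing the gene copies; the deficit p-value compares
    the sampled heterozygote counts to the observed count using the mid-p
    convention (ties counted with weight 1/2), which keeps null p-values
    approximately uniform despite the discreteness of the statistic.
    Returns NaN for a monomorphic locus.
    """
    sub = table if group is None else table.subset(group=group)
    l = [loc.name for loc in sub.loci].index(locus)
    col = sub.calls[:, l, :]
    copies = col[col[:, 0] != MISSING].ravel()
    if copies.size == 0 or np.unique(copies).size < 2:
        return float("nan")
    obs_het = int((col[:, 0] != col[:, 1])[col[:, 0] != MISSING].sum())
    rng = np.random.default_rng(seed)
    n_pairs = copies.size // 2
    score = 0.0
    block = max(1, min(n_iter, 2_000_000 // max(copies.size, 1)))
    done = 0
    while done < n_iter:
        b = min(block, n_iter - done)
        perm = np.array([rng.permutation(copies) for _ in range(b)])
        sim_het = (perm[:, 0 : 2 * n_pairs : 2] != perm[:, 1 : 2 * n_pairs : 2]).sum(axis=1)
        score += float((sim_het < obs_het).sum()) + 0.5 * float((sim_het == obs_het).sum())
        done += b
    return (0.5 + score) / (1 + n_iter)
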