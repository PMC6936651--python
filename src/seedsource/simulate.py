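"""Synthetic genotype, stand and climate generators.

These emulate the structure of the study system the package targets: a
native metapopulation of two diverged varieties, each split into three
regional clusters of several reference populations, scored at ~13 highly
polymorphic SSR loci; introduced stands with an adult cohort and a
naturally regenerated cohort with mapped coordinates; and a
populations x climate-variables table with a low-rank group structure.

Allele frequencies follow a hierarchical Balding-Nichols model: at each
level of the hierarchy (variety, cluster, population) frequencies are
drawn Dirichlet around the parent level with concentration (1-F)/F, so the
differentiation parameter F at each level is directly controllable and
testable.  All generators are pure functions of (spec, seed) and emit
truth labels (origins, pedigree, group memberships) alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import CoordinateSet, GenotypeTable, Locus

#: the ten climate descriptors used for the climate-space analyses
CLIMATE_VARIABLES = [
    "bFFP", "TD", "MSP", "PAS", "FFP", "eFFP", "DD<0", "EMT", "MCMT", "NFFD",
]


@dataclass
class MetapopSpec:
    """Hierarchy and divergence of the synthetic native metapopulation.

    FST defaults follow the expected ordering variety > cluster >
    population; allele counts per locus default to the 5-15 range typical
    of highly polymorphic SSRs.
    """

    n_varieties: int = 2
    clusters_per_variety: int = 3
    pops_per_cluster: int = 6
    n_loci: int = 13
    alleles_per_locus: tuple[int, int] = (5, 15)
    n_per_pop: int = 20
    fst_within_cluster: float = 0.015
    fst_between_cluster: float = 0.04
    fst_between_variety: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        fs = (self.fst_within_cluster, self.fst_between_cluster, self.fst_between_variety)
        if not all(0 < f < 1 for f in fs):
            raise ValueError("all FST values must be in (0, 1)")
        if not (fs[2] > fs[1] > fs[0]):
            raise ValueError("divergence must be ordered variety > cluster > population")


@dataclass
class Metapopulation:
    """A generated metapopulation: genotypes plus the latent truth."""

    table: GenotypeTable
    pop_labels: list[str]
    pop_variety: dict[str, str]
    pop_cluster: dict[str, str]
    # latent allele-frequency hierarchy, per locus: arrays over allele codes
    ancestral: list[np.ndarray]
    variety_freqs: dict[str, list[np.ndarray]]
    cluster_freqs: dict[str, list[np.ndarray]]
    pop_freqs: dict[str, list[np.ndarray]]
    allele_codes: list[np.ndarray]


def _dirichlet_child(rng: np.random.Generator, parent: np.ndarray, fst: float) -> np.ndarray:
    conc = parent * (1.0 - fst) / fst
    # Dirichlet with tiny concentrations can underflow to all-zero; clip.
    child = rng.dirichlet(np.clip(conc, 1e-6, None))
    child = np.clip(child, 1e-9, None)
    return child / child.sum()


def _draw_genotypes(
    rng: np.random.Generator, freqs: list[np.ndarray], codes: list[np.ndarray], n: int
) -> np.ndarray:
    L = len(freqs)
    calls = np.zeros((n, L, 2), dtype=int)
    for l in range(L):
        idx = rng.choice(len(freqs[l]), size=(n, 2), p=freqs[l])
        calls[:, l, :] = codes[l][idx]
    return calls


def generate_metapopulation(spec: MetapopSpec) -> Metapopulation:
    """Sample the frequency hierarchy and HWE genotypes for every population."""
    rng = np.random.default_rng(spec.seed)
    ancestral, codes = [], []
    for l in range(spec.n_loci):
        n_all = int(rng.integers(spec.alleles_per_locus[0], spec.alleles_per_locus[1] + 1))
        # concentration > 1 keeps ancestral frequencies fairly even, giving
        # the high within-population gene diversity typical of SSR panels
        ancestral.append(rng.dirichlet(np.full(n_all, 3.0)))
        # allele codes mimic fragment sizes: distinct, <= 999
        codes.append(np.sort(rng.choice(np.arange(80, 400), size=n_all, replace=False)))

    variety_freqs: dict[str, list[np.ndarray]] = {}
    cluster_freqs: dict[str, list[np.ndarray]] = {}
    pop_freqs: dict[str, list[np.ndarray]] = {}
    pop_variety: dict[str, str] = {}
    pop_cluster: dict[str, str] = {}
    pop_labels: list[str] = []

    variety_names = ["coastal", "interior"][: spec.n_varieties] or [
        f"variety{v+1}" for v in range(spec.n_varieties)
    ]
    if spec.n_varieties > 2:
        variety_names = [f"variety{v+1}" for v in range(spec.n_varieties)]
    pop_no = 0
    for v, vname in enumerate(variety_names):
        variety_freqs[vname] = [
            _dirichlet_child(rng, ancestral[l], spec.fst_between_variety)
            for l in range(spec.n_loci)
        ]
        for c in range(spec.clusters_per_variety):
            cname = f"{vname}-C{c+1}"
            cluster_freqs[cname] = [
                _dirichlet_child(rng, variety_freqs[vname][l], spec.fst_between_cluster)
                for l in range(spec.n_loci)
            ]
            for p in range(spec.pops_per_cluster):
                pop_no += 1
                pname = f"R{pop_no:02d}"
                pop_freqs[pname] = [
                    _dirichlet_child(rng, cluster_freqs[cname][l], spec.fst_within_cluster)
                    for l in range(spec.n_loci)
                ]
                pop_variety[pname] = vname
                pop_cluster[pname] = cname
                pop_labels.append(pname)

    individuals, groups, blocks = [], [], []
    for pname in pop_labels:
        calls = _draw_genotypes(rng, pop_freqs[pname], codes, spec.n_per_pop)
        blocks.append(calls)
        individuals.extend(f"{pname}-{k+1:03d}" for k in range(spec.n_per_pop))
        groups.extend([pname] * spec.n_per_pop)
    table = GenotypeTable.from_calls(
        individuals,
        [f"SSR{l+1:02d}" for l in range(spec.n_loci)],
        np.concatenate(blocks, axis=0),
        groups,
    )
    return Metapopulation(
        table=table,
        pop_labels=pop_labels,
        pop_variety=pop_variety,
        pop_cluster=pop_cluster,
        ancestral=ancestral,
        variety_freqs=variety_freqs,
        cluster_freqs=cluster_freqs,
        pop_freqs=pop_freqs,
        allele_codes=codes,
    )


# ---------------------------------------------------------------------- #
# Introduced stand with adults + regeneration, coordinates and pedigree
# ---------------------------------------------------------------------- #


@dataclass
class StandSpec:
    """An introduced stand: planted adults plus naturally regenerated offspring.

    ``source_mixture`` maps source population labels (of a metapopulation)
    to adult-origin proportions.  Offspring positions follow a Gaussian
    seed kernel of scale ``sigma_seed`` around the mother; fathers are
    drawn among adults with Gaussian pollen-kernel weights of scale
    ``sigma_pollen``, or replaced by an immigrant gamete from the mixture
    frequencies with probability ``immigrant_fraction``.
    """

    name: str = "E1"
    n_adults: int = 40
    source_mixture: dict[str, float] = field(default_factory=dict)
    extent: float = 160.0
    n_offspring: int = 40
    sigma_seed: float = 10.0
    sigma_pollen: float = 30.0
    immigrant_fraction: float = 0.3
    selfing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.source_mixture:
            tot = sum(self.source_mixture.values())
            if not np.isclose(tot, 1.0):
                raise ValueError("source_mixture proportions must sum to 1")
        if self.sigma_seed <= 0 or self.sigma_pollen <= 0:
            raise ValueError("dispersal kernels must be positive")


@dataclass
class Stand:
    """A generated stand: genotypes, coordinates, and the true pedigree."""

    table: GenotypeTable  # adults (cohort "adult") + offspring ("regeneration")
    coords: CoordinateSet
    mothers: dict[str, str]  # offspring id -> adult id
    fathers: dict[str, str | None]  # None = immigrant pollen
    adult_origin: dict[str, str]  # adult id -> source population label

    @property
    def adults(self) -> GenotypeTable:
        return self.table.subset(cohort="adult")

    @property
    def offspring(self) -> GenotypeTable:
        return self.table.subset(cohort="regeneration")


def _mixture_freqs(metapop: Metapopulation, mixture: dict[str, float]) -> list[np.ndarray]:
    L = len(metapop.ancestral)
    out = []
    for l in range(L):
        f = np.zeros_like(metapop.ancestral[l])
        for pop, w in mixture.items():
            f += w * metapop.pop_freqs[pop][l]
        out.append(f / f.sum())
    return out


def generate_stand(spec: StandSpec, metapop: Metapopulation) -> Stand:
    """Simulate adults, a mating/dispersal process, and offspring genotypes."""
    rng = np.random.default_rng(spec.seed)
    mixture = spec.source_mixture or {metapop.pop_labels[0]: 1.0}
    unknown = set(mixture) - set(metapop.pop_labels)
    if unknown:
        raise ValueError(f"unknown source populations: {sorted(unknown)}")
    pops = list(mixture)
    probs = np.array([mixture[p] for p in pops])
    codes = metapop.allele_codes
    L = len(codes)

    adult_ids = [f"{spec.name}-A{k+1:03d}" for k in range(spec.n_adults)]
    adult_origin = {}
    adult_calls = np.zeros((spec.n_adults, L, 2), dtype=int)
    for k, aid in enumerate(adult_ids):
        src = pops[rng.choice(len(pops), p=probs)]
        adult_origin[aid] = src
        adult_calls[k] = _draw_genotypes(rng, metapop.pop_freqs[src], codes, 1)[0]
    adult_xy = rng.uniform(0.0, spec.extent, size=(spec.n_adults, 2))

    mix_freqs = _mixture_freqs(metapop, mixture)
    off_ids = [f"{spec.name}-O{k+1:03d}" for k in range(spec.n_offspring)]
    off_calls = np.zeros((spec.n_offspring, L, 2), dtype=int)
    off_xy = np.zeros((spec.n_offspring, 2))
    mothers: dict[str, str] = {}
    fathers: dict[str, str | None] = {}
    for k, oid in enumerate(off_ids):
        m = int(rng.integers(spec.n_adults))
        mothers[oid] = adult_ids[m]
        off_xy[k] = adult_xy[m] + rng.normal(0.0, spec.sigma_seed, size=2)
        if rng.random() < spec.selfing_rate:
            f_idx: int | None = m
        elif rng.random() < spec.immigrant_fraction:
            f_idx = None
        else:
            d2 = np.sum((adult_xy - adult_xy[m]) ** 2, axis=1)
            w = np.exp(-d2 / (2.0 * spec.sigma_pollen**2))
            w[m] = 0.0  # outcrossing unless the selfing branch was taken
            f_idx = int(rng.choice(spec.n_adults, p=w / w.sum()))
        fathers[oid] = adult_ids[f_idx] if f_idx is not None else None
        for l in range(L):
            maternal = adult_calls[m, l, rng.integers(2)]
            if f_idx is None:
                paternal = codes[l][rng.choice(len(mix_freqs[l]), p=mix_freqs[l])]
            else:
                paternal = adult_calls[f_idx, l, rng.integers(2)]
            off_calls[k, l] = (maternal, paternal)

    table = GenotypeTable.from_calls(
        adult_ids + off_ids,
        [f"SSR{l+1:02d}" for l in range(L)],
        np.concatenate([adult_calls, off_calls], axis=0),
        [spec.name] * (spec.n_adults + spec.n_offspring),
        ["adult"] * spec.n_adults + ["regeneration"] * spec.n_offspring,
    )
    coords = CoordinateSet(adult_ids + off_ids, np.concatenate([adult_xy, off_xy], axis=0))
    return Stand(table, coords, mothers, fathers, adult_origin)


# ---------------------------------------------------------------------- #
# Climate table with a latent group/factor structure
# ---------------------------------------------------------------------- #


def generate_climate(
    groups: dict[str, list[str]],
    n_vars: int = 10,
    separation: float = 6.0,
    noise: float = 0.1,
    n_factors: int = 4,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Populations x climate-variables table from a latent factor model.

    ``groups`` maps group names to lists of population labels.  Group means
    form a balanced simplex (rows of a Hadamard design) with pairwise
    distance ``separation`` factor-SDs, so between-group variance is
    spread evenly over the factor axes; variables are random loadings on
    the factors plus Gaussian noise of SD ``noise``.  Returns the table
    and the truth map population -> group.  Variable names use the
    standard climate descriptor set when ``n_vars == 10``.
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    from scipy.linalg import hadamard

    rng = np.random.default_rng(seed)
    names = list(groups)
    pops, truth = [], {}
    for g in names:
        for p in groups[g]:
            pops.append(p)
            truth[p] = g
    n = len(pops)
    size = 1
    while size < max(len(names), n_factors):
        size *= 2
    h = hadamard(size)[: len(names), :n_factors].astype(float)
    # rows of H are mutually orthogonal: pairwise center distance is
    # sqrt(2 * n_factors) * scale for distinct rows
    scale = separation / np.sqrt(2 * min(n_factors, size))
    centers = h * scale
    factors = np.array([centers[names.index(truth[p])] for p in pops])
    factors = factors + rng.normal(size=(n, n_factors))
    # orthonormal loadings keep the factor geometry isotropic in variable
    # space, so standardization and eigenvalue weighting do not crush any
    # single between-group contrast
    loadings, _ = np.linalg.qr(rng.normal(size=(n_vars, n_factors)))
    data = factors @ loadings.T + noise * rng.normal(size=(n, n_vars))
    var_names = (
        CLIMATE_VARIABLES if n_vars == len(CLIMATE_VARIABLES) else [f"V{j+1}" for j in range(n_vars)]
    )
    return pd.DataFrame(data, index=pops, columns=var_names), truth
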