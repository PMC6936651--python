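import numpy as np
import pytest

import seedsource as ss


@pytest.fixture(scope="session")
def metapop():
    """Default synthetic metapopulation (2 varieties x 3 clusters x 6 pops)."""
    return ss.generate_metapopulation(ss.MetapopSpec(seed=11))


@pytest.fixture(scope="session")
def diverged_metapop():
    """Strongly diverged varieties: many effectively private alleles."""
    spec = ss.MetapopSpec(
        fst_between_variety=0.35,
        fst_between_cluster=0.10,
        fst_within_cluster=0.03,
        alleles_per_locus=(8, 15),
        n_per_pop=24,
        seed=23,
    )
    return ss.generate_metapopulation(spec)


@pytest.fixture(scope="session")
def diagnostic_metapop():
    """Moderate population divergence with high retained diversity: the
    regime where 13 SSR loci are jointly diagnostic of the source
    population."""
    spec = ss.MetapopSpec(
        fst_between_variety=0.18,
        fst_between_cluster=0.14,
        fst_within_cluster=0.12,
        alleles_per_locus=(12, 18),
        n_per_pop=40,
        seed=23,
    )
    return ss.generate_metapopulation(spec)


@pytest.fixture(scope="session")
def stand(metapop):
    """One introduced stand with adults, offspring, coordinates, pedigree."""
    spec = ss.StandSpec(
        name="E1",
        source_mixture={"R01": 0.7, "R02": 0.3},
        n_adults=40,
        n_offspring=40,
        sigma_seed=5.0,
        sigma_pollen=30.0,
        immigrant_fraction=0.2,
        seed=31,
    )
    return ss.generate_stand(spec, metapop)


@pytest.fixture
def tiny_table():
    """Two individuals, one locus: {AA, AB} with alleles 90/100."""
    calls = np.array([[[90, 90]], [[90, 100]]])
    return ss.GenotypeTable.from_calls(["i1", "i2"], ["L1"], calls, ["p1", "p1"])


def make_table(rng, n_ind=12, n_loci=3, n_alleles=4, groups=None, missing=0.0):
    """Random small genotype table for round-trip / oracle tests."""
    alleles = rng.choice(np.arange(50, 999), size=(n_loci, n_alleles), replace=False)
    calls = np.zeros((n_ind, n_loci, 2), dtype=int)
    for l in range(n_loci):
        calls[:, l, :] = rng.choice(alleles[l], size=(n_ind, 2))
    if missing > 0:
        mask = rng.random((n_ind, n_loci)) < missing
        calls[mask] = 0
    if groups is None:
        groups = ["g1"] * (n_ind // 2) + ["g2"] * (n_ind - n_ind // 2)
    ids = [f"ind{k:02d}" for k in range(n_ind)]
    return ss.GenotypeTable.from_calls(ids, [f"L{l}" for l in range(n_loci)], calls, groups)
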