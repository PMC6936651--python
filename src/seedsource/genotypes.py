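"""Core data model and I/O for codominant multiallelic genotypes.

Genotypes are diploid calls at microsatellite (SSR) loci: an unordered
pair of integer allele codes (typically fragment sizes), with 0 marking a
missing call.  Individuals carry a population/cohort label and, optionally,
planar coordinates in metres.  Interchange formats are the GENEPOP dialect
(read and write) and the two-row-per-individual STRUCTURE layout (read
only); coordinates travel as an ``id,x,y`` CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = 0


class GenepopFormatError(ValueError):
    """Raised when a GENEPOP file violates the dialect."""


@dataclass(frozen=True)
class Locus:
    """A codominant locus with its observed allele codes.

    Allele codes are positive integers (fragment sizes); the missing code 0
    is never a member of :attr:`alleles`.
    """

    name: str
    alleles: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.alleles) == 0:
            raise ValueError(f"locus {self.name!r} has no alleles")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"locus {self.name!r} has duplicate allele codes")
        if MISSING in self.alleles or any(a < 0 for a in self.alleles):
            raise ValueError(f"locus {self.name!r}: allele codes must be positive")


@dataclass
class CoordinateSet:
    """Planar coordinates (metres, local projection) for named individuals."""

    ids: list[str]
    xy: np.ndarray  # (n, 2) float

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.shape != (len(self.ids), 2):
            raise ValueError("xy must be (n, 2) matching ids")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("coordinates must be finite")
        self._index = {i: k for k, i in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise ValueError("duplicate individual id in coordinates")

    def __contains__(self, ind: str) -> bool:
        return ind in self._index

    def get(self, ind: str) -> np.ndarray:
        return self.xy[self._index[ind]]

    def subset(self, ids: Sequence[str]) -> "CoordinateSet":
        return CoordinateSet(list(ids), np.array([self.get(i) for i in ids]))

    @classmethod
    def read_csv(cls, path: str | Path) -> "CoordinateSet":
        df = pd.read_csv(path)
        cols = [c.strip().lower() for c in df.columns]
        df.columns = cols
        return cls(df["id"].astype(str).tolist(), df[["x", "y"]].to_numpy(float))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"id": self.ids, "x": self.xy[:, 0], "y": self.xy[:, 1]}).to_csv(
            path, index=False
        )


class AlleleFrequencies:
    """Per-locus allele frequencies of one population sample.

    ``freqs[l]`` maps allele code -> frequency among the observed gene
    copies at locus ``l`` (missing calls excluded); ``copies[l]`` is the
    number of gene copies counted.  Loci where every call was missing have
    an empty mapping and 0 copies and are flagged in :attr:`empty_loci`.
    """

    def __init__(self, loci: Sequence[Locus], freqs: list[dict[int, float]], copies: np.ndarray):
        self.loci = list(loci)
        self.freqs = freqs
        self.copies = np.asarray(copies, dtype=int)
        self.empty_loci = [l.name for l, f in zip(self.loci, freqs) if not f]

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def freq(self, locus_index: int, allele: int) -> float:
        return self.freqs[locus_index].get(allele, 0.0)

    def counts(self, locus_index: int) -> dict[int, float]:
        """Gene-copy counts per allele (frequency times copies)."""
        n = self.copies[locus_index]
        return {a: p * n for a, p in self.freqs[locus_index].items()}


class GenotypeTable:
    """Individuals x loci table of diploid allele-pair calls.

    Parameters
    ----------
    individuals : unique individual identifiers.
    loci : the loci, in column order.
    calls : integer array (n_individuals, n_loci, 2); 0 marks a missing
        call (both entries are then 0).
    groups : population label per individual.
    cohorts : optional per-individual cohort flag (e.g. "adult" /
        "regeneration").
    """

    def __init__(
        self,
        individuals: Sequence[str],
        loci: Sequence[Locus],
        calls: np.ndarray,
        groups: Sequence[str],
        cohorts: Sequence[str] | None = None,
    ):
        self.individuals = list(individuals)
        self.loci = list(loci)
        self.calls = np.asarray(calls, dtype=int)
        self.groups = list(groups)
        self.cohorts = list(cohorts) if cohorts is not None else None
        n, L = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(f"calls must have shape ({n}, {L}, 2)")
        if len(self.groups) != n:
            raise ValueError("groups must match individuals")
        if self.cohorts is not None and len(self.cohorts) != n:
            raise ValueError("cohorts must match individuals")
        if len(set(self.individuals)) != n:
            raise ValueError("duplicate individual ID")
        self._index = {ind: k for k, ind in enumerate(self.individuals)}
        for l, locus in enumerate(self.loci):
            observed = set(self.calls[:, l, :].ravel().tolist()) - {MISSING}
            extra = observed - set(locus.alleles)
            if extra:
                raise ValueError(
                    f"locus {locus.name!r}: calls contain alleles {sorted(extra)} "
                    "not declared for the locus"
                )

    # ------------------------------------------------------------------ #

    @classmethod
    def from_calls(
        cls,
        individuals: Sequence[str],
        locus_names: Sequence[str],
        calls: np.ndarray,
        groups: Sequence[str],
        cohorts: Sequence[str] | None = None,
    ) -> "GenotypeTable":
        """Build a table inferring each locus's allele set from the calls."""
        calls = np.asarray(calls, dtype=int)
        loci = []
        for l, name in enumerate(locus_names):
            observed = sorted(set(calls[:, l, :].ravel().tolist()) - {MISSING})
            if not observed:
                observed = [1]  # placeholder allele for an all-missing column
            loci.append(Locus(name, tuple(observed)))
        return cls(individuals, loci, calls, groups, cohorts)

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def group_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def index_of(self, individual: str) -> int:
        return self._index[individual]

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L): True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    def n_typed(self) -> np.ndarray:
        """Number of genotyped (non-missing) loci per individual."""
        return (~self.missing_mask()).sum(axis=1)

    def subset(
        self,
        group: str | None = None,
        cohort: str | None = None,
        indices: Sequence[int] | None = None,
    ) -> "GenotypeTable":
        mask = np.ones(len(self), dtype=bool)
        if group is not None:
            mask &= np.array([g == group for g in self.groups])
        if cohort is not None:
            if self.cohorts is None:
                raise ValueError("table has no cohort labels")
            mask &= np.array([c == cohort for c in self.cohorts])
        idx = np.flatnonzero(mask)
        if indices is not None:
            idx = idx[np.asarray(indices)]
        return GenotypeTable(
            [self.individuals[i] for i in idx],
            self.loci,
            self.calls[idx],
            [self.groups[i] for i in idx],
            [self.cohorts[i] for i in idx] if self.cohorts is not None else None,
        )

    def allele_frequencies(self, group: str | None = None) -> AlleleFrequencies:
        """Observed allele frequencies over gene copies, missing excluded.

        Loci where every call is missing are returned with an empty
        frequency mapping and flagged for downstream exclusion.
        """
        table = self if group is None else self.subset(group=group)
        if len(table) == 0:
            raise ValueError(f"group {group!r} has no individuals")
        freqs: list[dict[int, float]] = []
        copies = np.zeros(table.n_loci, dtype=int)
        for l in range(table.n_loci):
            col = table.calls[:, l, :]
            obs = col[col[:, 0] != MISSING].ravel()
            copies[l] = obs.size
            if obs.size == 0:
                freqs.append({})
                continue
            alleles, counts = np.unique(obs, return_counts=True)
            freqs.append({int(a): c / obs.size for a, c in zip(alleles, counts)})
        return AlleleFrequencies(table.loci, freqs, copies)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        calls_a = np.sort(self.calls, axis=2)
        calls_b = np.sort(other.calls, axis=2)
        return (
            self.individuals == other.individuals
            and [l.name for l in self.loci] == [l.name for l in other.loci]
            and [set(l.alleles) for l in self.loci] == [set(l.alleles) for l in other.loci]
            and np.array_equal(calls_a, calls_b)
            and self.groups == other.groups
        )


def concat_tables(tables: Iterable[GenotypeTable]) -> GenotypeTable:
    """Stack tables sharing the same locus names (allele sets are unioned)."""
    tables = list(tables)
    names = [l.name for l in tables[0].loci]
    for t in tables[1:]:
        if [l.name for l in t.loci] != names:
            raise ValueError("tables must share locus names in order")
    inds = sum((t.individuals for t in tables), [])
    groups = sum((t.groups for t in tables), [])
    cohorts = None
    if all(t.cohorts is not None for t in tables):
        cohorts = sum((t.cohorts for t in tables), [])
    calls = np.concatenate([t.calls for t in tables], axis=0)
    return GenotypeTable.from_calls(inds, names, calls, groups, cohorts)


# ---------------------------------------------------------------------- #
# GENEPOP dialect
# ---------------------------------------------------------------------- #


def _parse_allele_field(field: str, lineno: int) -> tuple[int, int]:
    if len(field) == 4:
        w = 2
    elif len(field) == 6:
        w = 3
    else:
        raise GenepopFormatError(
            f"line {lineno}: allele field {field!r} has width {len(field)}, "
            "expected 4 (2-digit) or 6 (3-digit)"
        )
    try:
        a1, a2 = int(field[:w]), int(field[w:])
    except ValueError as exc:
        raise GenepopFormatError(f"line {lineno}: non-numeric allele field {field!r}") from exc
    if a1 == MISSING or a2 == MISSING:
        return (MISSING, MISSING)
    return (a1, a2)


def read_genepop(path: str | Path) -> GenotypeTable:
    """Read a GENEPOP file (2- or 3-digit allele codes, 00/000 = missing).

    Populations appear in file order.  If text follows a ``Pop`` separator
    on the same line it is used as the population name, otherwise
    populations are named ``pop1``, ``pop2``, ...
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenepopFormatError("empty file")
    locus_names: list[str] = []
    i = 1  # skip title
    while i < len(lines):
        stripped = lines[i].strip()
        if stripped.lower() == "pop" or stripped.lower().startswith("pop "):
            break
        if stripped:
            locus_names.extend(s.strip() for s in stripped.split(",") if s.strip())
        i += 1
    if i == len(lines):
        raise GenepopFormatError("no 'Pop' separator found")
    individuals: list[str] = []
    groups: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_counter = 0
    current_pop = ""
    while i < len(lines):
        stripped = lines[i].strip()
        lineno = i + 1
        if stripped.lower() == "pop" or stripped.lower().startswith("pop "):
            pop_counter += 1
            name = stripped[3:].strip()
            current_pop = name if name else f"pop{pop_counter}"
            i += 1
            continue
        if not stripped:
            i += 1
            continue
        if "," not in stripped:
            raise GenepopFormatError(f"line {lineno}: expected 'id , genotypes' row")
        ind_id, geno = stripped.split(",", 1)
        ind_id = ind_id.strip()
        if ind_id in individuals:
            raise ValueError(f"line {lineno}: duplicate individual ID {ind_id!r}")
        fields = geno.split()
        if len(fields) != len(locus_names):
            raise GenepopFormatError(
                f"line {lineno}: {len(fields)} genotype fields for {len(locus_names)} loci"
            )
        rows.append([_parse_allele_field(f, lineno) for f in fields])
        individuals.append(ind_id)
        groups.append(current_pop)
        i += 1
    if not individuals:
        raise GenepopFormatError("no individuals found")
    calls = np.array(rows, dtype=int)
    return GenotypeTable.from_calls(individuals, locus_names, calls, groups)


def write_genepop(
    table: GenotypeTable,
    path: str | Path,
    title: str = "seedsource export",
    groups: Sequence[str] | None = None,
) -> None:
    """Write a GENEPOP file with 3-digit zero-padded allele codes.

    Output is byte-stable for identical input; population names are carried
    on the ``Pop`` separator lines so that :func:`read_genepop` round-trips
    losslessly.
    """
    group_order = list(groups) if groups is not None else table.group_names
    for locus in table.loci:
        if any(a > 999 for a in locus.alleles):
            raise ValueError(f"locus {locus.name!r} has allele code > 999")
    out = [title]
    out.extend(l.name for l in table.loci)
    for g in group_order:
        idx = [k for k, grp in enumerate(table.groups) if grp == g]
        if not idx:
            raise ValueError(f"population {g!r} is empty")
        out.append(f"Pop {g}")
        for k in idx:
            fields = []
            for l in range(table.n_loci):
                a1, a2 = table.calls[k, l]
                fields.append(f"{a1:03d}{a2:03d}")
            out.append(f"{table.individuals[k]} , " + " ".join(fields))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------- #
# STRUCTURE two-row layout (reader only)
# ---------------------------------------------------------------------- #


def read_structure(path: str | Path, locus_names: Sequence[str] | None = None) -> GenotypeTable:
    """Read the two-row-per-individual STRUCTURE text layout.

    Each individual occupies two whitespace-separated rows: id, integer
    population code, then one allele per locus; -9 marks a missing allele.
    An optional header row of locus names is used when present (detected by
    a first row that is one column shorter than the data rows).
    """
    raw = [ln.split() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not raw:
        raise ValueError("empty STRUCTURE file")
    if locus_names is None and len(raw) > 1 and len(raw[0]) == len(raw[1]) - 2:
        locus_names = raw[0]
        raw = raw[1:]
    if len(raw) % 2 != 0:
        raise ValueError("STRUCTURE file must have two rows per individual")
    n_loci = len(raw[0]) - 2
    if locus_names is None:
        locus_names = [f"L{l + 1}" for l in range(n_loci)]
    individuals, groups, rows = [], [], []
    for r in range(0, len(raw), 2):
        top, bot = raw[r], raw[r + 1]
        if top[0] != bot[0]:
            raise ValueError(f"rows {r + 1}/{r + 2}: individual ids differ")
        if len(top) != n_loci + 2 or len(bot) != n_loci + 2:
            raise ValueError(f"individual {top[0]!r}: inconsistent column count")
        individuals.append(top[0])
        groups.append(f"pop{top[1]}")
        calls = []
        for l in range(n_loci):
            a1, a2 = int(top[2 + l]), int(bot[2 + l])
            if a1 < 0 or a2 < 0:
                calls.append((MISSING, MISSING))
            else:
                calls.append((a1, a2))
        rows.append(calls)
    return GenotypeTable.from_calls(individuals, list(locus_names), np.array(rows, int), groups)
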