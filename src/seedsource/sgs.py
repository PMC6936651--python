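"""Fine-scale spatial genetic structure (SGS).

Pairwise kinship between mapped individuals is measured with the Loiselle
estimator (a frequency-weighted correlation of allele dosages with a
small-sample bias term), regressed on the logarithm of spatial distance to
give the slope b_log, whose significance is obtained by permuting the
spatial positions of individuals (a Mantel-style test).  The strength of
SGS is summarized by Sp = -b_log / (1 - F1), with F1 the mean kinship of
the shortest distance class, and visualized as a distance-class
correlogram with a permutation envelope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, CoordinateSet, GenotypeTable

DEFAULT_CLASS_EDGES = (5.0, 10.0, 20.0, 40.0, 80.0, 160.0)


@dataclass
class KinshipMatrix:
    """Multilocus Loiselle kinship with per-locus components.

    ``per_locus[l]`` is the n x n kinship matrix at locus l (NaN where an
    individual is untyped); ``weights[l]`` the locus weight sum_a p(1-p);
    ``multilocus`` the weight-averaged matrix over the loci typed in both
    members of each pair.
    """

    individuals: list[str]
    multilocus: np.ndarray
    per_locus: np.ndarray  # (L, n, n)
    weights: np.ndarray  # (L,)
    excluded_loci: list[str] = field(default_factory=list)

    def pair_values(self) -> tuple[np.ndarray, np.ndarray]:
        """Upper-triangle (i, j) index arrays of valid pairs."""
        n = len(self.individuals)
        iu, ju = np.triu_indices(n, k=1)
        ok = np.isfinite(self.multilocus[iu, ju])
        return iu[ok], ju[ok]


def loiselle_kinship(table: GenotypeTable, group: str | None = None) -> KinshipMatrix:
    """Pairwise multilocus Loiselle kinship within a group.

    Reference allele frequencies are taken from the analysed group itself.
    Per locus: F_ij = [sum_a (x_ia - p_a)(x_ja - p_a) + sum_a p_a(1-p_a)/(n-1)]
    / sum_a p_a(1-p_a), with x the allele dosages in {0, 0.5, 1} and n the
    gene copies observed at the locus.  Multilocus values weight loci by
    sum_a p_a(1-p_a); monomorphic loci get weight 0 and are excluded.
    """
    sub = table if group is None else table.subset(group=group)
    n = len(sub)
    if n < 3:
        raise ValueError("need at least 3 individuals")
    L = sub.n_loci
    per_locus = np.full((L, n, n), np.nan)
    weights = np.zeros(L)
    excluded = []
    for l in range(L):
        col = sub.calls[:, l, :]
        typed = col[:, 0] != MISSING
        copies = col[typed].ravel()
        if copies.size == 0 or np.unique(copies).size < 2:
            excluded.append(sub.loci[l].name)
            continue
        alleles = np.unique(copies)
        # dosage matrix: 0 / 0.5 / 1 per allele, NaN rows when untyped
        x = np.full((n, alleles.size), np.nan)
        x[typed] = 0.5 * (
            (col[typed, 0][:, None] == alleles).astype(float)
            + (col[typed, 1][:, None] == alleles).astype(float)
        )
        p = x[typed].mean(axis=0)
        denom = float(np.sum(p * (1.0 - p)))
        if denom <= 0:
            excluded.append(sub.loci[l].name)
            continue
        n_copies = copies.size
        bias = denom / (n_copies - 1)
        c = x - p
        c_f = np.nan_to_num(c)
        num = c_f @ c_f.T + bias
        mat = num / denom
        invalid = ~typed
        mat[invalid, :] = np.nan
        mat[:, invalid] = np.nan
        per_locus[l] = mat
        weights[l] = denom
    if not np.any(weights > 0):
        raise ValueError("no polymorphic locus available for kinship")
    valid = np.isfinite(per_locus)
    w = weights[:, None, None] * valid
    with np.errstate(invalid="ignore"):
        multilocus = np.nansum(per_locus * w, axis=0) / np.sum(w, axis=0)
    np.fill_diagonal(multilocus, np.nan)
    return KinshipMatrix(sub.individuals, multilocus, per_locus, weights, excluded)


def sp_statistic(b_log: float, f_first_class: float) -> float:
    """Sp = -b_log / (1 - F1); F1 is the mean kinship of the first class."""
    if f_first_class >= 1.0:
        raise ValueError("first-class mean kinship must be < 1")
    return -b_log / (1.0 - f_first_class)


def _slope(lnd: np.ndarray, f: np.ndarray) -> float:
    x = lnd - lnd.mean()
    return float(np.dot(x, f - f.mean()) / np.dot(x, x))


def _pair_distances(xy: np.ndarray, iu: np.ndarray, ju: np.ndarray) -> np.ndarray:
    return np.linalg.norm(xy[iu] - xy[ju], axis=1)


@dataclass
class SGSResults:
    """Fitted spatial-genetic-structure results for one cohort."""

    group: str
    n_individuals: int
    n_pairs: int
    f_first: float
    b_log: float
    se_b: float
    p_value: float
    sp: float
    correlogram: pd.DataFrame  # per class: mean F, n pairs, envelope
    class_edges: tuple[float, ...]
    n_perm: int

    def summary(self) -> str:
        lines = [f"Spatial genetic structure: {self.group}", "-" * 40]
        lines.append(f"individuals / pairs : {self.n_individuals} / {self.n_pairs}")
        lines.append(f"F(first class)      : {self.f_first:.4f}")
        lines.append(f"b_log (+/- SE)      : {self.b_log:.4f} ({self.se_b:.4f})")
        lines.append(f"permutation p       : {self.p_value:.4f}  ({self.n_perm} permutations)")
        lines.append(f"Sp                  : {self.sp:.4f}")
        lines.append("")
        lines.append(self.correlogram.to_string(float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)


class SGSModel:
    """SGS analysis of one mapped cohort.

    Parameters
    ----------
    table, coords : genotypes and planar coordinates (m); individuals of
        the analysed group must all be present in ``coords``.
    group, cohort : optional subsetting of the table.
    class_edges : upper bounds of the distance classes; classes are
        left-open right-closed starting at 0.
    max_dist : optionally drop pairs beyond this distance from the
        regression (all pairs enter by default).
    """

    def __init__(
        self,
        table: GenotypeTable,
        coords: CoordinateSet,
        group: str | None = None,
        cohort: str | None = None,
        class_edges: tuple[float, ...] = DEFAULT_CLASS_EDGES,
        max_dist: float | None = None,
    ):
        self.table = table.subset(group=group, cohort=cohort) if (group or cohort) else table
        self.coords = coords.subset(self.table.individuals)
        self.group = group or "(all)"
        self.class_edges = tuple(class_edges)
        self.max_dist = max_dist

    def fit(self, n_perm: int = 10_000, seed: int | None = None) -> SGSResults:
        kin = loiselle_kinship(self.table)
        xy = self.coords.xy.copy()
        # coincident points have no defined log-distance: jitter by 1 cm
        _, first_idx = np.unique(np.round(xy, 9), axis=0, return_index=True)
        if first_idx.size < xy.shape[0]:
            warnings.warn("coincident coordinates jittered by 0.01 m")
            dup = np.setdiff1d(np.arange(xy.shape[0]), first_idx)
            jit = np.random.default_rng(0).normal(0.0, 0.01, size=(dup.size, 2))
            xy[dup] += jit
        iu, ju = kin.pair_values()
        d = _pair_distances(xy, iu, ju)
        if self.max_dist is not None:
            keep = d <= self.max_dist
            iu, ju, d = iu[keep], ju[keep], d[keep]
        if np.unique(np.round(d, 12)).size < 2:
            raise ValueError("need at least 2 distinct pairwise distances")
        f = kin.multilocus[iu, ju]
        lnd = np.log(d)
        b_obs = _slope(lnd, f)

        se_b = self._jackknife_se(kin, iu, ju, lnd)
        p_value, perm_class_means = self._permute(kin, xy, iu, ju, f, b_obs, n_perm, seed)
        corr = self._correlogram(d, f, perm_class_means)
        f_first = float(corr["mean_F"].iloc[0])
        return SGSResults(
            group=self.group,
            n_individuals=len(self.table),
            n_pairs=int(iu.size),
            f_first=f_first,
            b_log=b_obs,
            se_b=se_b,
            p_value=p_value,
            sp=sp_statistic(b_obs, f_first) if np.isfinite(f_first) else np.nan,
            correlogram=corr,
            class_edges=self.class_edges,
            n_perm=n_perm,
        )

    # ------------------------------------------------------------------ #

    def _jackknife_se(self, kin: KinshipMatrix, iu, ju, lnd) -> float:
        """Delete-one-locus jackknife SE of the regression slope."""
        L = kin.per_locus.shape[0]
        used = np.flatnonzero(kin.weights > 0)
        if used.size < 2:
            return float("nan")
        per_pair = kin.per_locus[:, iu, ju]  # (L, P)
        valid = np.isfinite(per_pair)
        w = kin.weights[:, None] * valid
        num = np.nansum(np.nan_to_num(per_pair) * w, axis=0)
        den = np.sum(w, axis=0)
        slopes = []
        for l in used:
            wn = num - np.nan_to_num(per_pair[l]) * w[l]
            wd = den - w[l]
            ok = wd > 0
            slopes.append(_slope(lnd[ok], wn[ok] / wd[ok]))
        slopes_arr = np.array(slopes)
        m = used.size
        return float(np.sqrt((m - 1) / m * np.sum((slopes_arr - slopes_arr.mean()) ** 2)))

    def _class_index(self, d: np.ndarray) -> np.ndarray:
        # classes are (lo, hi]; searchsorted with side='left' maps d == edge
        # into the class ending at that edge
        idx = np.searchsorted(np.asarray(self.class_edges), d, side="left")
        idx[d > self.class_edges[-1]] = len(self.class_edges)
        return idx

    def _permute(self, kin, xy, iu, ju, f, b_obs, n_perm, seed):
        """Shuffle spatial positions among individuals; slope and class means."""
        rng = np.random.default_rng(seed)
        n = xy.shape[0]
        n_classes = len(self.class_edges)
        le = 0
        class_means = np.full((n_perm, n_classes), np.nan)
        for s in range(n_perm):
            perm = rng.permutation(n)
            d_perm = _pair_distances(xy[perm], iu, ju)
            if self.max_dist is not None:
                keep = d_perm <= self.max_dist
            else:
                keep = slice(None)
            dp, fp = d_perm[keep], f[keep]
            if np.unique(np.round(dp, 12)).size >= 2:
                if _slope(np.log(dp), fp) <= b_obs:
                    le += 1
            ci = self._class_index(dp)
            for c in range(n_classes):
                sel = ci == c
                if sel.any():
                    class_means[s, c] = fp[sel].mean()
        p = (1 + le) / (1 + n_perm) if n_perm > 0 else float("nan")
        return p, class_means

    def _correlogram(self, d, f, perm_class_means) -> pd.DataFrame:
        edges = (0.0,) + self.class_edges
        ci = self._class_index(d)
        rows = []
        for c in range(len(self.class_edges)):
            sel = ci == c
            env = perm_class_means[:, c]
            env = env[np.isfinite(env)]
            rows.append(
                {
                    "class": f"({edges[c]:g}, {edges[c + 1]:g}]",
                    "n_pairs": int(sel.sum()),
                    "mean_F": float(f[sel].mean()) if sel.any() else np.nan,
                    "env_lo": float(np.percentile(env, 2.5)) if env.size else np.nan,
                    "env_hi": float(np.percentile(env, 97.5)) if env.size else np.nan,
                }
            )
        return pd.DataFrame(rows).set_index("class")


def plot_correlogram(result: SGSResults, ax=None):
    """Distance-class correlogram with the permutation envelope (matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    df = result.correlogram
    x = np.arange(len(df))
    ax.plot(x, df["mean_F"], "o-", label="mean kinship")
    ax.fill_between(x, df["env_lo"], df["env_hi"], alpha=0.2, label="95% envelope")
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xticks(x, df.index, rotation=45)
    ax.set_xlabel("distance class (m)")
    ax.set_ylabel(r"$F_{ij}$")
    ax.set_title(f"{result.group}: Sp = {result.sp:.4f}")
    ax.legend()
    return ax
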