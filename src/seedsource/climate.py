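"""Climate-space construction and climatic-distance comparison.

Populations are embedded in a low-dimensional climate space by principal
component analysis of standardized climate variables; pairwise climatic
distances are Euclidean distances over the retained components weighted by
their (normalized) eigenvalues.  The distance matrix supports UPGMA
dendrograms and the expected-vs-realized distance comparison: a G-test
asks whether the climatic distances from introduced stands to their
genetically assigned source populations differ from the distances expected
if seed had been drawn at random from any putative origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

DEFAULT_VAR_FRACTION = 0.97


@dataclass
class ClimateSpace:
    """PC scores and eigenvalues of populations in climate space.

    ``weighting`` controls how eigenvalues enter :meth:`distance`:
    "share" (normalized eigenvalue share, default), "eigenvalue" (raw
    lambda) or "sqrt" (sqrt of lambda).
    """

    populations: list[str]
    variables: list[str]
    standardized: pd.DataFrame
    scores: pd.DataFrame  # populations x retained PCs
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    n_retained: int
    var_fraction: float
    weighting: str = "share"
    loadings: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def explained_fraction(self) -> float:
        return float(self.eigenvalues[: self.n_retained].sum() / self.eigenvalues.sum())

    def _weights(self) -> np.ndarray:
        lam = self.eigenvalues[: self.n_retained]
        if self.weighting == "share":
            return lam / lam.sum()
        if self.weighting == "eigenvalue":
            return lam
        if self.weighting == "sqrt":
            return np.sqrt(lam)
        raise ValueError(f"unknown weighting {self.weighting!r}")

    def distance(self, i: str, j: str) -> float:
        """Eigenvalue-weighted Euclidean distance between two populations."""
        w = self._weights()
        diff = self.scores.loc[i].to_numpy() - self.scores.loc[j].to_numpy()
        return float(np.sqrt(np.sum(w * diff**2)))

    def distance_matrix(self) -> pd.DataFrame:
        from scipy.spatial.distance import pdist

        w = self._weights()
        x = self.scores.to_numpy() * np.sqrt(w)
        mat = squareform(pdist(x))
        return pd.DataFrame(mat, index=self.populations, columns=self.populations)


def build_climate_space(
    table: pd.DataFrame,
    var_fraction: float = DEFAULT_VAR_FRACTION,
    fit_on: list[str] | None = None,
    weighting: str = "share",
) -> ClimateSpace:
    """PCA of standardized climate variables.

    Variables are z-scored (correlation-structure PCA, appropriate for
    mixed units); the smallest number of components whose cumulative
    explained variance reaches ``var_fraction`` is retained.  When
    ``fit_on`` names a subset of populations (e.g. the native range), the
    PCA is fitted on that subset and the remaining populations are
    projected into it.
    """
    if table.isna().any().any():
        raise ValueError("climate table has missing values")
    if len(table) < 2:
        raise ValueError("need at least 2 populations")
    fit = table.loc[fit_on] if fit_on is not None else table
    mu = fit.mean(axis=0)
    sd = fit.std(axis=0, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant climate variable(s): {constant}")
    z_fit = (fit - mu) / sd
    z_all = (table - mu) / sd
    u, s, vt = np.linalg.svd(z_fit.to_numpy(), full_matrices=False)
    eig = s**2 / (len(fit) - 1)
    cum = np.cumsum(eig) / eig.sum()
    n_retained = int(np.searchsorted(cum, var_fraction - 1e-12) + 1)
    comps = vt[:n_retained]
    scores = z_all.to_numpy() @ comps.T
    pc_names = [f"PC{k+1}" for k in range(n_retained)]
    return ClimateSpace(
        populations=list(table.index),
        variables=list(table.columns),
        standardized=z_all,
        scores=pd.DataFrame(scores, index=table.index, columns=pc_names),
        eigenvalues=eig,
        n_retained=n_retained,
        var_fraction=var_fraction,
        weighting=weighting,
        loadings=pd.DataFrame(comps.T, index=table.columns, columns=pc_names),
    )


def weighted_distance(space: ClimateSpace, i: str, j: str) -> float:
    """Eigenvalue-weighted Euclidean distance in a climate space."""
    return space.distance(i, j)


# ---------------------------------------------------------------------- #
# UPGMA dendrogram
# ---------------------------------------------------------------------- #


def upgma(dist: pd.DataFrame) -> str:
    """Average-linkage (UPGMA) dendrogram of a symmetric distance matrix.

    Returns a rooted ultrametric newick string with branch lengths; tip
    depth equals half the cophenetic distance.  Ties are resolved
    deterministically by processing labels in input order.
    """
    mat = dist.to_numpy(dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if np.any(mat < 0):
        raise ValueError("distances must be non-negative")
    labels = list(dist.index)
    linkage = hierarchy.linkage(squareform(mat, checks=False), method="average")
    tree = hierarchy.to_tree(linkage)

    def newick(node, parent_height: float) -> str:
        height = node.dist / 2.0
        length = parent_height - height
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.10g}"
        left = newick(node.get_left(), height)
        right = newick(node.get_right(), height)
        return f"({left},{right}):{length:.10g}"

    root_height = tree.dist / 2.0
    left = newick(tree.get_left(), root_height)
    right = newick(tree.get_right(), root_height)
    return f"({left},{right});"


# ---------------------------------------------------------------------- #
# Expected vs realized climatic distances, G-test
# ---------------------------------------------------------------------- #


@dataclass
class DistanceComparison:
    """Expected vs realized climatic-distance distributions with a G-test."""

    expected: np.ndarray
    realized: np.ndarray
    bin_edges: np.ndarray
    observed_counts: np.ndarray
    expected_counts: np.ndarray  # rescaled to the realized total
    g: float
    df: int
    p_value: float

    def summary(self) -> str:
        lines = ["Expected vs realized climatic distances", "-" * 40]
        lines.append(f"expected pairs : {self.expected.size}")
        lines.append(f"realized pairs : {self.realized.size}")
        lines.append(f"G = {self.g:.4f}, df = {self.df}, p = {self.p_value:.4f}")
        return "\n".join(lines)


def g_test(observed: np.ndarray, expected: np.ndarray) -> tuple[float, int, float]:
    """Likelihood-ratio goodness-of-fit G = 2 sum O ln(O/E).

    ``expected`` is rescaled to the observed total; bins with O = 0
    contribute nothing, bins with E = 0 must have been merged upstream.
    df = (number of non-empty bins) - 1.
    """
    o = np.asarray(observed, float)
    e = np.asarray(expected, float)
    if np.any((e == 0) & (o > 0)):
        raise ValueError("bin with observed counts but zero expectation; merge bins first")
    e = e * o.sum() / e.sum()
    mask = o > 0
    g = float(2.0 * np.sum(o[mask] * np.log(o[mask] / e[mask])))
    nonempty = int(np.sum((o > 0) | (e > 0)))
    df = nonempty - 1
    p = float(stats.chi2.sf(g, df)) if df > 0 else 1.0
    return g, df, p


def _merge_empty_bins(edges: np.ndarray, o: np.ndarray, e: np.ndarray):
    """Merge bins with zero expected count into their left neighbour."""
    edges = list(edges)
    o = list(o)
    e = list(e)
    i = 0
    merged = False
    while i < len(o):
        if e[i] == 0:
            merged = True
            if i > 0:
                o[i - 1] += o.pop(i)
                e[i - 1] += e.pop(i)
                edges.pop(i)
            elif len(o) > 1:
                o[1] += o.pop(0)
                e[1] += e.pop(0)
                edges.pop(1)
            else:
                break
        else:
            i += 1
    if merged:
        warnings.warn("bins with zero expected count merged into neighbours")
    return np.array(edges), np.array(o, float), np.array(e, float)


def expected_realized_gtest(
    space: ClimateSpace,
    stands: list[str],
    putative_origins: list[str],
    realized_map: dict[str, str],
    n_bins: int = 10,
    bin_edges: np.ndarray | None = None,
) -> DistanceComparison:
    """G-test of realized vs expected climatic-distance distributions.

    The expected distribution collects the climatic distances from every
    stand to every putative origin (seed drawn by chance from any origin);
    the realized distribution collects the distances from each stand to
    its genetically assigned origin(s).  Histograms share equal-width bins
    over the pooled range (``n_bins`` by default, or explicit
    ``bin_edges``); bins with zero expectation are merged.
    """
    bad = set(realized_map.values()) - set(putative_origins)
    if bad:
        raise ValueError(f"assigned origins not among putative origins: {sorted(bad)}")
    expected = np.array(
        [space.distance(s, o) for s in stands for o in putative_origins]
    )
    realized = np.array([space.distance(s, o) for s, o in realized_map.items()])
    if bin_edges is None:
        if n_bins < 2:
            raise ValueError("need at least 2 bins")
        lo, hi = float(expected.min()), float(expected.max())
        if lo == hi:
            raise ValueError("all climatic distances identical; no histogram possible")
        bin_edges = np.linspace(lo, hi, n_bins + 1)
    e_counts, _ = np.histogram(expected, bins=bin_edges)
    o_counts, _ = np.histogram(realized, bins=bin_edges)
    edges, o_m, e_m = _merge_empty_bins(bin_edges, o_counts, e_counts)
    g, df, p = g_test(o_m, e_m)
    return DistanceComparison(
        expected=expected,
        realized=realized,
        bin_edges=np.asarray(edges),
        observed_counts=o_m,
        expected_counts=e_m * o_m.sum() / e_m.sum(),
        g=g,
        df=df,
        p_value=p,
    )
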