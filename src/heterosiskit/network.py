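"""Unsigned weighted co-expression network, modules and trait correlation.

The pipeline mirrors the classic weighted-network workflow: keep the most
variant features, raise |Pearson r| to a soft power chosen for approximate
scale-free topology, convert adjacency to topological overlap (TOM),
cluster 1 - TOM by average linkage, cut into modules, summarize each module
by its eigengene (first principal component of the standardized member
expression) and correlate eigengenes with sample traits.

Module detection uses a simplified cut rather than the dynamic hybrid tree
cut: the dendrogram is cut at the 0.99 quantile of merge heights, clusters
below the minimum size are set unassigned (module 0), clusters without
internal cohesion are likewise dropped, and remaining modules are merged
while any two eigengenes correlate above 1 - merge_cut_height. Cohesion is
judged against the independence null: for uncorrelated Gaussian features
over n samples, E|r| ~= sqrt(2/pi)/sqrt(n - 1), and a cluster is kept only
when its mean within-cluster |r| exceeds ``cohesion_factor`` times that
expectation. The cohesion rule is what keeps an unstructured (pure-noise)
matrix from yielding one giant spurious module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


@dataclass
class NetworkConfig:
    variance_fraction: float = 0.40
    soft_power: int | str = "auto"   # "auto" or an integer >= 1
    min_module_size: int = 50
    merge_cut_height: float = 0.25
    edge_fraction: float = 0.01
    cut_quantile: float = 0.99
    cohesion_factor: float = 2.0
    scale_free_r2: float = 0.8

    def validate(self) -> None:
        for name in ("variance_fraction", "edge_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.soft_power != "auto":
            if int(self.soft_power) != self.soft_power or self.soft_power < 1:
                raise ValueError("soft_power must be 'auto' or an integer >= 1")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")


def log_normalized(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """log2(normalized count + 1) — the variance-stabilized input scale."""
    from heterosiskit.de import size_factors

    if factors is None:
        factors = size_factors(counts)
    arr = np.log2(counts.to_numpy(dtype=float) / factors.to_numpy() + 1.0)
    return pd.DataFrame(arr, index=counts.index, columns=counts.columns)


def variance_filter(expression: pd.DataFrame, fraction: float = 0.40) -> pd.DataFrame:
    """Keep the ceil(fraction * n) most variant features.

    Ties in variance are broken by feature id (lexicographically smaller
    wins) so the selection is deterministic.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    n_keep = int(np.ceil(fraction * len(expression)))
    var = expression.var(axis=1, ddof=1)
    order = sorted(expression.index, key=lambda f: (-var[f], f))
    keep = order[:n_keep]
    return expression.loc[keep]


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10 p(k) vs log10 k over equal-width connectivity bins."""
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    ok = counts > 0
    if ok.sum() < 3:
        return 0.0
    x = np.log10(centers[ok])
    y = np.log10(counts[ok] / counts.sum())
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def pick_soft_power(
    corr_abs: np.ndarray, r2_min: float = 0.8, fallback: int = 6
) -> int:
    """Smallest beta in 1..20 whose degree distribution looks scale-free."""
    for beta in range(1, 21):
        adj = corr_abs**beta
        k = adj.sum(axis=1) - 1.0  # exclude self
        if _scale_free_r2(k) >= r2_min:
            return beta
    warnings.warn(
        f"no soft power in 1..20 reached scale-free R^2 >= {r2_min}; using {fallback}",
        RuntimeWarning,
        stacklevel=2,
    )
    return fallback


def tom_from_adjacency(adj: np.ndarray) -> np.ndarray:
    """Topological overlap of an adjacency matrix with entries in [0, 1].

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with the
    sum over u distinct from i and j and k the row connectivity excluding
    the diagonal; TOM_ii = 1.
    """
    a0 = adj.astype(float).copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    shared = a0 @ a0  # zero diagonal makes the u=i and u=j terms vanish
    numer = shared + a0
    denom = np.minimum.outer(k, k) + 1.0 - a0
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, numer / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip((tom + tom.T) / 2.0, 0.0, 1.0)


def build_network(
    expression: pd.DataFrame, soft_power: int | str = "auto", r2_min: float = 0.8
) -> tuple[np.ndarray, np.ndarray, int]:
    """Unsigned adjacency |cor|^beta and its topological overlap matrix.

    Returns (adjacency, TOM, beta); beta is chosen for scale-free fit when
    soft_power="auto".
    """
    if expression.shape[1] < 3:
        raise ValueError("need at least 3 samples to build a network")
    corr = np.abs(np.corrcoef(expression.to_numpy(dtype=float)))
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    if soft_power == "auto":
        beta = pick_soft_power(corr, r2_min=r2_min)
    else:
        beta = int(soft_power)
    adj = corr**beta
    np.fill_diagonal(adj, 1.0)
    return adj, tom_from_adjacency(adj), beta


def detect_modules(tom: np.ndarray, expression: pd.DataFrame,
                   config: NetworkConfig | None = None) -> pd.Series:
    """Assign each feature a module id (0 = unassigned).

    Average-linkage clustering of 1 - TOM, cut at the configured quantile
    of merge heights; small or non-cohesive clusters go to module 0;
    surviving modules are merged while their eigengenes correlate above
    1 - merge_cut_height. Module ids are relabelled 1..M by decreasing
    size with feature order as tie-break, so permuting the input features
    permutes the assignment consistently.
    """
    config = config or NetworkConfig()
    config.validate()
    n = tom.shape[0]
    if tom.shape != (n, n) or not np.allclose(tom, tom.T, atol=1e-10):
        raise ValueError("TOM must be square and symmetric")
    if n != len(expression):
        raise ValueError("TOM size must match expression rows")

    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    heights = z[:, 2]
    cut = float(np.quantile(heights, config.cut_quantile))
    labels = fcluster(z, t=cut, criterion="distance")

    # size + cohesion screen; cohesion compares mean within-cluster |r|
    # to its expectation under feature independence
    arr = expression.to_numpy(dtype=float)
    n_samples = arr.shape[1]
    null_abs_r = np.sqrt(2.0 / np.pi) / np.sqrt(n_samples - 1)
    assignment = np.zeros(n, dtype=int)
    for lab in np.unique(labels):
        members = np.where(labels == lab)[0]
        if len(members) < config.min_module_size:
            continue
        with np.errstate(invalid="ignore"):
            c = np.abs(np.corrcoef(arr[members]))
        c = np.nan_to_num(c, nan=0.0)
        within = c[~np.eye(len(members), dtype=bool)].mean()
        if within < config.cohesion_factor * null_abs_r:
            continue
        assignment[members] = lab

    assignment = _relabel(assignment)
    assignment = _merge_modules(assignment, expression, config.merge_cut_height)
    return pd.Series(_relabel(assignment), index=expression.index, name="module")


def _relabel(assignment: np.ndarray) -> np.ndarray:
    """Relabel modules 1..M by decreasing size (first-occurrence tie-break)."""
    out = np.zeros_like(assignment)
    labs = [l for l in np.unique(assignment) if l != 0]
    sizes = {l: (assignment == l).sum() for l in labs}
    first = {l: int(np.argmax(assignment == l)) for l in labs}
    for new, lab in enumerate(
        sorted(labs, key=lambda l: (-sizes[l], first[l])), start=1
    ):
        out[assignment == lab] = new
    return out


def _merge_modules(
    assignment: np.ndarray, expression: pd.DataFrame, merge_cut_height: float
) -> np.ndarray:
    """Iteratively merge the most correlated eigengene pair above threshold."""
    assignment = assignment.copy()
    threshold = 1.0 - merge_cut_height
    while True:
        labs = [l for l in np.unique(assignment) if l != 0]
        if len(labs) < 2:
            return assignment
        eig = module_eigengenes(
            expression, pd.Series(assignment, index=expression.index)
        )
        best, best_r = None, threshold
        for i, a in enumerate(labs):
            for b in labs[i + 1:]:
                r = float(np.corrcoef(eig[a], eig[b])[0, 1])
                if r > best_r:
                    best, best_r = (a, b), r
        if best is None:
            return assignment
        a, b = best
        assignment[assignment == b] = a


def module_eigengenes(
    expression: pd.DataFrame, assignment: pd.Series
) -> dict[int, np.ndarray]:
    """First principal component per module, over samples.

    Features are standardized (mean 0, sd 1 across samples); the eigengene
    is the leading right-singular direction of the module submatrix,
    rescaled to unit variance and sign-oriented so its mean correlation
    with member features is positive.
    """
    out: dict[int, np.ndarray] = {}
    arr = expression.to_numpy(dtype=float)
    for lab in sorted(set(assignment) - {0}):
        members = np.where(assignment.to_numpy() == lab)[0]
        sub = arr[members]
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd == 0):
            bad = expression.index[members[np.where(sd.ravel() == 0)[0]]]
            raise ValueError(
                f"module {lab} contains constant features: {list(bad[:5])}"
            )
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        eig = vt[0]
        eig = eig / eig.std(ddof=1)
        corrs = [np.corrcoef(eig, row)[0, 1] for row in z]
        if np.mean(corrs) < 0:
            eig = -eig
        out[lab] = eig
    return out


def module_trait(
    eigengenes: dict[int, np.ndarray], traits: pd.DataFrame | pd.Series
) -> pd.DataFrame:
    """Pearson correlation and p-value per module × trait.

    p from t = r sqrt(n - 2) / sqrt(1 - r^2) on n - 2 df, two-sided.
    Zero-variance traits are flagged with NaN r and p.
    """
    if isinstance(traits, pd.Series):
        traits = traits.to_frame()
    rows = []
    for lab, eig in eigengenes.items():
        for trait in traits.columns:
            y = traits[trait].to_numpy(dtype=float)
            n = len(y)
            if np.std(y) == 0:
                rows.append({"module": lab, "trait": trait,
                             "r": np.nan, "p_value": np.nan,
                             "flag": "zero_variance_trait"})
                continue
            r = float(np.corrcoef(eig, y)[0, 1])
            r_c = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
            t = r_c * np.sqrt(n - 2) / np.sqrt(1.0 - r_c * r_c)
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
            rows.append({"module": lab, "trait": trait, "r": r,
                         "p_value": p, "flag": ""})
    return pd.DataFrame(rows)


def top_edges(
    expression: pd.DataFrame,
    assignment: pd.Series,
    fraction: float = 0.01,
    scope: str = "per_module",
) -> pd.DataFrame:
    """Strongest co-expression edges for visualization.

    Ranks feature pairs by |Pearson r| and keeps the top ``fraction``
    (ceiling, at least one edge per nonempty module) — within each module
    by default, or globally over assigned features with scope="global".
    """
    if scope not in ("per_module", "global"):
        raise ValueError(f"unknown scope {scope!r}")
    arr = expression.to_numpy(dtype=float)
    ids = expression.index.to_numpy()
    labels = assignment.to_numpy()
    rows = []

    def _edges(members: np.ndarray, module_label) -> None:
        if len(members) < 2:
            return
        corr = np.corrcoef(arr[members])
        iu = np.triu_indices(len(members), k=1)
        r = corr[iu]
        n_pairs = len(r)
        n_keep = max(1, int(np.ceil(fraction * n_pairs)))
        order = np.argsort(-np.abs(r), kind="mergesort")[:n_keep]
        for o in order:
            i, j = iu[0][o], iu[1][o]
            rows.append(
                {
                    "feature_a": ids[members[i]],
                    "feature_b": ids[members[j]],
                    "r": float(r[o]),
                    "module": module_label,
                }
            )

    if scope == "per_module":
        for lab in sorted(set(labels) - {0}):
            _edges(np.where(labels == lab)[0], lab)
    else:
        _edges(np.where(labels != 0)[0], "all")
    return pd.DataFrame(rows, columns=["feature_a", "feature_b", "r", "module"])
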