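"""Two-group differential expression on negative-binomial counts.

A deliberately small, fully documented test: median-of-ratios size factors,
per-gene method-of-moments NB dispersion shrunk halfway to a trimmed-mean
prior, a Wald test on the log2 fold change with a delta-method standard
error, and Benjamini–Hochberg FDR control. It is not a DESeq2 clone — no
trended dispersion fit, no LFC shrinkage, no independent filtering — but it
applies the same call criteria (adjusted p below alpha and |log2FC| above a
minimum) so the inheritance classifier downstream is self-contained and
every step is checkable by hand.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

_LN2 = math.log(2.0)
_DISPERSION_FLOOR = 1e-8


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample normalization factors.

    For each feature with all-positive counts, the ratio of each sample's
    count to the feature's geometric mean is formed; a sample's factor is
    the median ratio, rescaled so the factors have geometric mean 1. When
    no feature is positive in every sample, upper-quartile scaling is used
    instead (with a warning); an all-zero matrix yields unit factors.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if positive.any():
        sub = mat[positive]
        log_geo = np.log(sub).mean(axis=1, keepdims=True)
        ratios = sub / np.exp(log_geo)
        factors = np.median(ratios, axis=0)
    else:
        warnings.warn(
            "no feature with all-positive counts; falling back to "
            "upper-quartile scaling",
            RuntimeWarning,
            stacklevel=2,
        )
        uq = np.array(
            [
                np.percentile(col[col > 0], 75) if (col > 0).any() else 1.0
                for col in mat.T
            ]
        )
        factors = uq
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order statistics,
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def _group_moments(norm: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sub = norm[:, idx]
    return sub.mean(axis=1), sub.var(axis=1, ddof=1)


def _pooled_dispersion(
    norm: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray
) -> np.ndarray:
    """Per-gene NB dispersion, method of moments pooled within the two groups,
    floored and shrunk 50/50 toward the 20%-trimmed mean across genes."""
    alphas = []
    weights = []
    for idx in (idx_a, idx_b):
        m, v = _group_moments(norm, idx)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (v - m) / np.square(m), 0.0)
        alphas.append(a)
        weights.append(len(idx) - 1)
    pooled = (weights[0] * alphas[0] + weights[1] * alphas[1]) / sum(weights)
    pooled = np.maximum(pooled, _DISPERSION_FLOOR)
    prior = float(stats.trim_mean(pooled, 0.2))
    prior = max(prior, _DISPERSION_FLOOR)
    return 0.5 * pooled + 0.5 * prior


def de_contrast(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Wald test of group_b vs group_a (positive log2fc = higher in b).

    Returns a table with columns feature_id, contrast, log2fc, se, wald_z,
    p_value, padj and call in {up, down, ns}; "up" means the SECOND-named
    group (group_b, listed first in the ``contrast`` string "b_vs_a") is
    higher. Group means of zero get a 0.5 pseudocount added to both means
    so fold changes stay finite and the test stays symmetric.
    """
    for g in (group_a, group_b):
        n_g = int((samples["group"] == g).sum())
        if n_g < 2:
            raise ValueError(f"group {g!r} has {n_g} samples; need >= 2")
    if factors is None:
        factors = size_factors(counts)
    norm = counts.to_numpy(dtype=float) / factors.to_numpy()

    sample_pos = {s: i for i, s in enumerate(counts.columns)}
    idx_a = np.array(
        [sample_pos[s] for s in samples.loc[samples["group"] == group_a, "sample_id"]]
    )
    idx_b = np.array(
        [sample_pos[s] for s in samples.loc[samples["group"] == group_b, "sample_id"]]
    )

    m_a, _ = _group_moments(norm, idx_a)
    m_b, _ = _group_moments(norm, idx_b)
    disp = _pooled_dispersion(norm, idx_a, idx_b)

    zero = (m_a == 0) | (m_b == 0)
    m_a_adj = np.where(zero, m_a + 0.5, m_a)
    m_b_adj = np.where(zero, m_b + 0.5, m_b)

    log2fc = np.log2(m_b_adj / m_a_adj)
    n_a, n_b = len(idx_a), len(idx_b)
    se = (1.0 / _LN2) * np.sqrt(
        (1.0 + disp * m_a_adj) / (n_a * m_a_adj)
        + (1.0 + disp * m_b_adj) / (n_b * m_b_adj)
    )
    with np.errstate(invalid="ignore"):
        wald_z = np.where(log2fc == 0.0, 0.0, log2fc / se)
    p = 2.0 * stats.norm.sf(np.abs(wald_z))
    padj = adjust_bh(p)

    call = np.full(len(counts), "ns", dtype=object)
    call[(padj < alpha) & (log2fc > lfc_min)] = "up"
    call[(padj < alpha) & (log2fc < -lfc_min)] = "down"

    return pd.DataFrame(
        {
            "feature_id": counts.index.to_numpy(),
            "contrast": f"{group_b}_vs_{group_a}",
            "log2fc": log2fc,
            "se": se,
            "wald_z": wald_z,
            "p_value": p,
            "padj": padj,
            "call": call,
        }
    )


#: the five standard contrasts of the reciprocal-cross design, as
#: (group_b, group_a) pairs: parental divergence plus each cross against
#: each parent.
STANDARD_CONTRASTS = [
    ("P2", "P1"),
    ("F1a", "P1"),
    ("F1a", "P2"),
    ("F1b", "P1"),
    ("F1b", "P2"),
]


def run_standard_contrasts(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
) -> dict[str, pd.DataFrame]:
    """All five standard contrasts with shared size factors."""
    factors = size_factors(counts)
    return {
        f"{b}_vs_{a}": de_contrast(
            counts, samples, a, b, alpha=alpha, lfc_min=lfc_min, factors=factors
        )
        for b, a in STANDARD_CONTRASTS
    }
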