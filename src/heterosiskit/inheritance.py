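"""Twelve-bin inheritance-mode classification of expression in hybrids.

Given three directional differential-expression calls for a feature —
parent 2 vs parent 1, F1 vs parent 1 and F1 vs parent 2, each in
{up, down, ns} with "up" meaning the first-named member is higher — the
feature falls into one of twelve classical bins (I–XII), is conserved
(all three ns), or is ambiguous (the 14 remaining combinations, e.g. F1
significantly above one parent and below the other while the parents do
not differ). The bins group into three inheritance patterns:

* additivity (IV, X): parents differ and the hybrid sits strictly between;
* dominance (III, V, IX, XI): the hybrid matches one parent and differs
  from the other;
* overdominance (I, II, VI, VII, VIII, XII): the hybrid is above (or
  below) both parents.

"Nonadditive" = dominance plus overdominance.
"""

from __future__ import annotations

import pandas as pd

_CALLS = ("up", "down", "ns")

#: (P2_vs_P1, F_vs_P1, F_vs_P2) -> bin
TRIPLE_TO_BIN = {
    ("ns", "up", "up"): "I",
    ("up", "up", "up"): "II",
    ("up", "up", "ns"): "III",
    ("up", "up", "down"): "IV",
    ("up", "ns", "down"): "V",
    ("up", "down", "down"): "VI",
    ("ns", "down", "down"): "VII",
    ("down", "down", "down"): "VIII",
    ("down", "down", "ns"): "IX",
    ("down", "down", "up"): "X",
    ("down", "ns", "up"): "XI",
    ("down", "up", "up"): "XII",
    ("ns", "ns", "ns"): "conserved",
}

BIN_TO_PATTERN = {
    "IV": "additive",
    "X": "additive",
    "III": "dominant",
    "V": "dominant",
    "IX": "dominant",
    "XI": "dominant",
    "I": "overdominant",
    "II": "overdominant",
    "VI": "overdominant",
    "VII": "overdominant",
    "VIII": "overdominant",
    "XII": "overdominant",
    "conserved": "conserved",
    "ambiguous": "ambiguous",
}

PATTERNS = ("additive", "dominant", "overdominant", "conserved", "ambiguous")


def classify_feature(
    call_p2_vs_p1: str, call_f_vs_p1: str, call_f_vs_p2: str
) -> tuple[str, str]:
    """Map one feature's three directional calls to (bin, pattern)."""
    triple = (call_p2_vs_p1, call_f_vs_p1, call_f_vs_p2)
    for c in triple:
        if c not in _CALLS:
            raise ValueError(f"invalid call token {c!r}; expected up/down/ns")
    bin_ = TRIPLE_TO_BIN.get(triple, "ambiguous")
    return bin_, BIN_TO_PATTERN[bin_]


def _check_orientation(table: pd.DataFrame, expected: str) -> None:
    found = set(table["contrast"].unique())
    if found != {expected}:
        raise ValueError(
            f"contrast orientation mismatch: expected {expected!r}, found {sorted(found)}"
        )


def classify_all(
    contrast_p2_vs_p1: pd.DataFrame,
    contrast_f_vs_p1: pd.DataFrame,
    contrast_f_vs_p2: pd.DataFrame,
    cross: str,
    parent1: str = "P1",
    parent2: str = "P2",
) -> pd.DataFrame:
    """Classify every feature of one cross from its three contrast tables.

    The tables must cover identical feature sets and be oriented as
    (P2 vs P1), (F vs P1), (F vs P2); the ``contrast`` column is checked
    against the expected labels so a reversed table cannot slip through.
    Returns one row per feature with the three calls, the bin, the pattern
    and ``de_any`` (True when the feature is differential in at least one
    of the three contrasts — the DEG/DEL universe used for proportions).
    """
    _check_orientation(contrast_p2_vs_p1, f"{parent2}_vs_{parent1}")
    _check_orientation(contrast_f_vs_p1, f"{cross}_vs_{parent1}")
    _check_orientation(contrast_f_vs_p2, f"{cross}_vs_{parent2}")

    tables = [
        t.set_index("feature_id")
        for t in (contrast_p2_vs_p1, contrast_f_vs_p1, contrast_f_vs_p2)
    ]
    base = tables[0].index
    for t in tables[1:]:
        if not base.equals(t.index):
            offenders = sorted(base.symmetric_difference(t.index))
            raise ValueError(f"feature sets differ between contrasts: {offenders[:10]}")

    calls = pd.DataFrame(
        {
            "call_p2_vs_p1": tables[0]["call"],
            "call_f_vs_p1": tables[1]["call"],
            "call_f_vs_p2": tables[2]["call"],
        }
    )
    triples = list(
        zip(calls["call_p2_vs_p1"], calls["call_f_vs_p1"], calls["call_f_vs_p2"])
    )
    bins = [TRIPLE_TO_BIN.get(t, "ambiguous") for t in triples]
    patterns = [BIN_TO_PATTERN[b] for b in bins]
    out = calls.reset_index()
    out["cross"] = cross
    out["bin"] = bins
    out["pattern"] = patterns
    out["de_any"] = [any(c != "ns" for c in t) for t in triples]
    return out


def summarize_crosses(calls_f1a: pd.DataFrame, calls_f1b: pd.DataFrame) -> dict:
    """Pattern counts/proportions per cross and shared/unique nonadditive sets.

    Proportions use the features differential in at least one of the three
    contrasts for that cross as denominator. Nonadditive sets (dominant or
    overdominant) are intersected across the reciprocal crosses by feature
    id.
    """
    out: dict = {"per_cross": {}}
    nonadd = {}
    for calls in (calls_f1a, calls_f1b):
        cross = calls["cross"].iloc[0] if len(calls) else "?"
        de = calls[calls["de_any"]]
        counts = de["pattern"].value_counts().to_dict()
        denom = len(de)
        props = {
            p: (counts.get(p, 0) / denom if denom else 0.0) for p in PATTERNS
        }
        na = set(calls.loc[calls["pattern"].isin(["dominant", "overdominant"]),
                           "feature_id"])
        nonadd[cross] = na
        out["per_cross"][cross] = {
            "counts": {p: counts.get(p, 0) for p in PATTERNS},
            "proportions": props,
            "n_de_any": denom,
            "nonadditive": na,
        }
    crosses = list(nonadd)
    shared = nonadd[crosses[0]] & nonadd[crosses[1]] if len(crosses) == 2 else set()
    out["shared_nonadditive"] = shared
    for c in crosses:
        out["per_cross"][c]["unique_nonadditive"] = nonadd[c] - shared
    return out
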