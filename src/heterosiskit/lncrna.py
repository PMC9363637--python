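"""lncRNA identification cascade and cis/trans target pairing.

The cascade refines an assembled transcript catalog in three pure stages:

1. basic filter — spliced length >= 200 bp, a definite strand, and an
   assembly class code in {i, u, x} (intronic / intergenic / antisense);
2. known matching — candidates whose sequence matches a reference lncRNA
   set (e.g. a database export) at full length are "known";
3. coding-potential consensus — the remainder become "putative" lncRNAs
   when CNCI, CPC and PLEK scores are all negative and the Pfam E-value
   criterion holds.

The published Pfam criterion requires E-value < 1e-5, which is the
signature of a confident protein-domain hit; because that likely inverts
the intended "no coding evidence" rule, both readings are implemented:
``pfam_logic="as_printed"`` (the default, E < 1e-5 required) and
``"no_hit_required"`` (E >= 1e-5 or absent required).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

RETAINED_CLASS_CODES = frozenset({"i", "u", "x"})
CLASS_CODE_TO_POSITION = {"u": "intergenic", "i": "intronic", "x": "antisense"}


def basic_filter(catalog: pd.DataFrame, min_length: int = 200) -> pd.DataFrame:
    """Length / strand / class-code filter.

    Retains transcripts with spliced_length >= min_length (200 bp exactly
    passes), strand '+' or '-', and class code in {i, u, x}. A missing
    class code never passes.
    """
    keep = (
        (catalog["spliced_length"] >= min_length)
        & catalog["strand"].isin(["+", "-"])
        & catalog["class_code"].isin(RETAINED_CLASS_CODES)
    )
    return catalog.loc[keep].reset_index(drop=True)


def _kmer(seq: str, k: int = 16) -> str:
    return seq[:k]


def match_known(
    candidates: pd.DataFrame,
    sequences: dict[str, str],
    reference: dict[str, str],
    identity_min: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split candidates into (known, remainder) by full-length sequence match.

    A candidate is "known" when an ungapped, full-length (coverage 1.0)
    alignment against some reference sequence reaches ``identity_min``
    (default 1.0 — exact match, served by a hash index). For relaxed
    identity, same-length references are compared position-wise after a
    shared-prefix k-mer prefilter. Candidates without a sequence are
    excluded from matching with a warning and fall into the remainder.
    """
    if not 0.0 < identity_min <= 1.0:
        raise ValueError("identity_min must lie in (0, 1]")
    exact = set(reference.values())
    by_len: dict[int, list[str]] = {}
    for seq in reference.values():
        by_len.setdefault(len(seq), []).append(seq)

    known_mask = []
    for tid in candidates["transcript_id"]:
        seq = sequences.get(tid)
        if seq is None:
            warnings.warn(
                f"candidate {tid} has no sequence; excluded from known-matching",
                RuntimeWarning,
                stacklevel=2,
            )
            known_mask.append(False)
            continue
        if seq in exact:
            known_mask.append(True)
            continue
        if identity_min >= 1.0:
            known_mask.append(False)
            continue
        hit = False
        max_mismatch = int((1.0 - identity_min) * len(seq) + 1e-9)
        k = min(16, len(seq))
        for ref in by_len.get(len(seq), []):
            # prefix prefilter: a k-mer can differ in at most max_mismatch bases
            if sum(a != b for a, b in zip(_kmer(seq, k), _kmer(ref, k))) > max_mismatch:
                continue
            same = sum(a == b for a, b in zip(seq, ref))
            if same / len(seq) >= identity_min:
                hit = True
                break
        known_mask.append(hit)

    known_mask = np.asarray(known_mask, dtype=bool)
    known = candidates.loc[known_mask].reset_index(drop=True)
    remainder = candidates.loc[~known_mask].reset_index(drop=True)
    return known, remainder


def coding_consensus(
    remainder: pd.DataFrame,
    scores: pd.DataFrame,
    pfam_logic: str = "as_printed",
) -> pd.DataFrame:
    """Putative lncRNAs by unanimous coding-potential consensus.

    Requires cnci < 0, cpc < 0 and plek < 0 (strict), plus the Pfam
    criterion: ``as_printed`` keeps pfam_evalue < 1e-5 strictly;
    ``no_hit_required`` keeps pfam_evalue >= 1e-5 or absent. Transcripts
    missing any of the three scores (or, under as_printed, the E-value)
    are excluded and the reason recorded in the returned table's
    ``reason`` column (rows with reason == "" are the putative set).
    """
    if pfam_logic not in ("as_printed", "no_hit_required"):
        raise ValueError(f"unknown pfam_logic {pfam_logic!r}")
    s = scores.set_index("transcript_id")
    reasons = []
    for tid in remainder["transcript_id"]:
        if tid not in s.index:
            reasons.append("no_scores")
            continue
        row = s.loc[tid]
        reason = ""
        for col in ("cnci", "cpc", "plek"):
            v = row[col]
            if pd.isna(v):
                reason = f"missing_{col}"
                break
            if not v < 0:
                reason = f"{col}_nonnegative"
                break
        if not reason:
            ev = row["pfam_evalue"]
            if pfam_logic == "as_printed":
                if pd.isna(ev):
                    reason = "missing_pfam"
                elif not ev < 1e-5:
                    reason = "pfam_evalue_too_large"
            else:
                if not (pd.isna(ev) or ev >= 1e-5):
                    reason = "pfam_domain_hit"
        reasons.append(reason)
    out = remainder.copy()
    out["reason"] = reasons
    return out


def positional_class(
    lncrnas: pd.DataFrame, gene_annotation: pd.DataFrame | None = None
) -> pd.Series:
    """Positional class per lncRNA: intergenic, intronic or antisense.

    Driven by the class code (u/i/x). For code '.' a coordinate fallback
    against a gene annotation (columns chrom, start, end, strand, plus
    optional exon spans exon_start/exon_end) is used: contained in an
    annotated gene body without exon overlap -> intronic; overlapping an
    exon on the opposite strand -> antisense; otherwise intergenic.
    """
    out = []
    for _, row in lncrnas.iterrows():
        code = row["class_code"]
        if code in CLASS_CODE_TO_POSITION:
            out.append(CLASS_CODE_TO_POSITION[code])
            continue
        label = "intergenic"
        if gene_annotation is not None:
            genes = gene_annotation[gene_annotation["chrom"] == row["chrom"]]
            for _, g in genes.iterrows():
                if row["start"] >= g["start"] and row["end"] <= g["end"]:
                    has_exons = "exon_start" in g and not pd.isna(g["exon_start"])
                    exon_overlap = False
                    if has_exons:
                        exon_overlap = (
                            row["start"] < g["exon_end"] and row["end"] > g["exon_start"]
                        )
                    if exon_overlap and g["strand"] != row["strand"]:
                        label = "antisense"
                        break
                    if not exon_overlap:
                        label = "intronic"
                        break
                elif (
                    "exon_start" in g
                    and not pd.isna(g["exon_start"])
                    and row["start"] < g["exon_end"]
                    and row["end"] > g["exon_start"]
                    and g["strand"] != row["strand"]
                ):
                    label = "antisense"
                    break
        out.append(label)
    return pd.Series(out, index=lncrnas.index, name="positional_class")


def summarize_catalog(
    catalog: pd.DataFrame, length_bins: list[int] | None = None
) -> dict:
    """Length histogram, exon-count distribution and per-chromosome shares."""
    if catalog.empty:
        raise ValueError("empty catalog")
    if length_bins is None:
        length_bins = list(range(0, 5001, 200)) + [np.inf]
    hist, edges = np.histogram(catalog["spliced_length"], bins=length_bins)
    n = len(catalog)
    chrom_counts = catalog["chrom"].value_counts()
    exon_counts = catalog["exon_count"].value_counts().sort_index()
    summary = {
        "n": n,
        "length_hist": {"edges": list(edges), "counts": hist.tolist()},
        "exon_count_pct": (exon_counts / n * 100.0).to_dict(),
        "chrom_pct": (chrom_counts / n * 100.0).to_dict(),
    }
    if "positional_class" in catalog:
        cls = catalog["positional_class"].value_counts()
        summary["class_pct"] = (cls / n * 100.0).to_dict()
    return summary


def genomic_gap(
    chrom_a: str, start_a: int, end_a: int, chrom_b: str, start_b: int, end_b: int
) -> float:
    """Distance between two 0-based half-open spans; 0 when overlapping,
    inf across chromosomes."""
    if chrom_a != chrom_b:
        return math.inf
    if start_a < end_b and start_b < end_a:
        return 0.0
    return float(max(start_a, start_b) - min(end_a, end_b))


def predict_targets(
    lncrnas: pd.DataFrame,
    genes: pd.DataFrame,
    expression: pd.DataFrame,
    factors: pd.Series | None = None,
    window: int = 100_000,
    r_min: float = 0.9,
) -> pd.DataFrame:
    """Cis/trans lncRNA–gene pairs by expression correlation and distance.

    Correlation is Pearson's r on log2(normalized count + 1) across all
    samples; pairs with |r| >= r_min are kept and labelled cis when on the
    same chromosome within ``window`` bp (gap 0 for overlap), else trans.
    Constant expression vectors make r undefined; such features are
    skipped with a warning.
    """
    from heterosiskit.de import size_factors as _sf

    if factors is None:
        factors = _sf(expression)
    log_expr = np.log2(expression.to_numpy(dtype=float) / factors.to_numpy() + 1.0)
    log_expr = pd.DataFrame(log_expr, index=expression.index, columns=expression.columns)

    rows = []
    for _, lnc in lncrnas.iterrows():
        lid = lnc["transcript_id"]
        if lid not in log_expr.index:
            continue
        x = log_expr.loc[lid].to_numpy()
        if np.std(x) == 0:
            warnings.warn(f"constant expression for {lid}; skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        for _, g in genes.iterrows():
            gid = g["gene_id"]
            if gid not in log_expr.index:
                continue
            y = log_expr.loc[gid].to_numpy()
            if np.std(y) == 0:
                warnings.warn(f"constant expression for {gid}; skipped",
                              RuntimeWarning, stacklevel=2)
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            if abs(r) < r_min:
                continue
            gap = genomic_gap(
                lnc["chrom"], lnc["start"], lnc["end"],
                g["chrom"], g["start"], g["end"],
            )
            mode = "cis" if gap <= window else "trans"
            rows.append(
                {
                    "lncrna_id": lid,
                    "gene_id": gid,
                    "mode": mode,
                    "distance": gap,
                    "r": r,
                }
            )
    return pd.DataFrame(rows, columns=["lncrna_id", "gene_id", "mode", "distance", "r"])


def build_catalog(
    catalog: pd.DataFrame,
    sequences: dict[str, str],
    reference: dict[str, str],
    scores: pd.DataFrame,
    min_length: int = 200,
    identity_min: float = 1.0,
    pfam_logic: str = "as_printed",
    gene_annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Run the full cascade; returns the catalog with status and class.

    status in {known, putative, rejected}; putative/known rows also carry
    a positional class. The ``reason`` column explains every rejection.
    """
    survivors = basic_filter(catalog, min_length=min_length)
    surviving_ids = set(survivors["transcript_id"])
    known, remainder = match_known(
        survivors, sequences, reference, identity_min=identity_min
    )
    consensus = coding_consensus(remainder, scores, pfam_logic=pfam_logic)

    out = catalog.copy()
    out["status"] = "rejected"
    out["reason"] = "basic_filter"
    out.loc[out["transcript_id"].isin(surviving_ids), "reason"] = ""
    out.loc[out["transcript_id"].isin(set(known["transcript_id"])), "status"] = "known"
    putative_ids = set(consensus.loc[consensus["reason"] == "", "transcript_id"])
    out.loc[out["transcript_id"].isin(putative_ids), "status"] = "putative"
    reason_map = dict(zip(consensus["transcript_id"], consensus["reason"]))
    out["reason"] = [
        reason_map.get(t, r) if t in reason_map else r
        for t, r in zip(out["transcript_id"], out["reason"])
    ]
    lnc = out["status"].isin(["known", "putative"])
    out.loc[lnc, "positional_class"] = positional_class(
        out.loc[lnc], gene_annotation
    )
    return out
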