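"""Readers and writers for the pipeline's file formats.

TSV for counts, sample tables, phenotypes, coding scores and results; GTF
(1-based inclusive on disk, converted to 0-based half-open internally) for
transcript models; FASTA for sequences; YAML for configuration; JSON for
the run manifest. Readers reject malformed input rather than coercing it,
and every writer round-trips losslessly through its paired reader.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from heterosiskit.simulate import GROUP_ALIASES, GROUPS

logger = logging.getLogger("heterosiskit")

CANONICAL_GROUPS = set(GROUPS)


def read_sample_table(path, group_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Sample table TSV with columns sample_id and group.

    User-facing group labels (e.g. breed codes WW/YY/WY/YW) are mapped to
    the canonical P1/P2/F1a/F1b via ``group_map`` (the breed aliases by
    default); labels already canonical pass through.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in table or "group" not in table:
        raise ValueError("sample table needs sample_id and group columns")
    if table["sample_id"].duplicated().any():
        dups = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    mapping = dict(GROUP_ALIASES if group_map is None else group_map)
    table["group"] = [
        g if g in CANONICAL_GROUPS else mapping.get(g, g) for g in table["group"]
    ]
    unknown = set(table["group"]) - CANONICAL_GROUPS
    if unknown:
        raise ValueError(f"unmapped group labels: {sorted(unknown)}")
    return table


def read_counts(path, sample_table_path, group_map: dict[str, str] | None = None):
    """Count matrix TSV (feature id + one integer column per sample).

    Columns are reordered to the sample-table order; a sample missing from
    the header, a duplicate feature id, or any non-integer or negative
    cell is an error.
    """
    samples = read_sample_table(sample_table_path, group_map=group_map)
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index.name = "feature_id"
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise ValueError(f"duplicate feature id: {dup!r}")
    missing = [s for s in samples["sample_id"] if s not in counts.columns]
    if missing:
        raise ValueError(f"samples missing from counts header: {missing}")
    counts = counts[list(samples["sample_id"])]
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        frac = arr.astype(float)
        if np.any(frac != np.floor(frac)) or np.any(~np.isfinite(frac)):
            bad = counts.columns[np.where(frac != np.floor(frac))[1][0]]
            raise ValueError(f"non-integer count found (column {bad!r})")
        counts = counts.astype(int)
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative count found")
    return counts, samples


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id")


def write_sample_table(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_phenotypes(path, group_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Phenotype TSV: individual_id, group, trait, value (one row each)."""
    pheno = pd.read_csv(path, sep="\t", dtype={"value": float})
    required = {"individual_id", "group", "trait", "value"}
    if not required <= set(pheno.columns):
        raise ValueError(f"phenotype table needs columns {sorted(required)}")
    if pheno.duplicated(["individual_id", "trait"]).any():
        raise ValueError("duplicate (individual, trait) measurement")
    mapping = dict(GROUP_ALIASES if group_map is None else group_map)
    pheno["group"] = [
        g if g in CANONICAL_GROUPS else mapping.get(g, g) for g in pheno["group"]
    ]
    return pheno


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def read_coding_scores(path) -> pd.DataFrame:
    """Coding-potential score TSV: transcript_id, cnci, cpc, plek, pfam_evalue.

    Missing cells are allowed (recorded as NaN); negative E-values and
    duplicate transcript ids are rejected.
    """
    scores = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "cnci", "cpc", "plek", "pfam_evalue"}
    if not required <= set(scores.columns):
        raise ValueError(f"score table needs columns {sorted(required)}")
    if scores["transcript_id"].duplicated().any():
        dup = scores.loc[scores["transcript_id"].duplicated(), "transcript_id"].iloc[0]
        raise ValueError(f"duplicate transcript_id in scores: {dup!r}")
    ev = scores["pfam_evalue"]
    if (ev.dropna() < 0).any():
        raise ValueError("negative Pfam E-value")
    return scores


def write_coding_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GTF / FASTA

def read_transcript_catalog(gtf_path, fasta_path=None):
    """Transcript catalog from a GTF (plus optional FASTA sequences).

    Each line is parsed with the gffutils feature parser so malformed
    lines are reported with their line number. Coordinates are converted
    from 1-based inclusive to 0-based half-open. Per transcript the
    catalog records chrom, span, strand, exon count, spliced length
    (sum of exon lengths) and the ``class_code`` attribute ('.' when
    absent). An exon outside its transcript's declared span expands the
    span with a warning. Returns ``(catalog, sequences)``.
    """
    transcripts: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise ValueError(
                    f"unparseable GTF line {lineno}: expected 9 tab-separated fields"
                )
            try:
                feat = feature_from_line(line)
                if feat.start is None or feat.end is None:
                    raise ValueError("missing coordinates")
            except Exception as exc:
                raise ValueError(f"unparseable GTF line {lineno}: {exc}") from exc
            start0, end0 = feat.start - 1, feat.end  # to 0-based half-open
            if feat.featuretype == "transcript":
                tid = feat.attributes["transcript_id"][0]
                code = feat.attributes.get("class_code", ["."])[0]
                transcripts[tid] = {
                    "transcript_id": tid,
                    "gene_id": feat.attributes.get("gene_id", [tid])[0],
                    "chrom": feat.seqid,
                    "start": start0,
                    "end": end0,
                    "strand": feat.strand if feat.strand in "+-" else ".",
                    "class_code": code,
                }
            elif feat.featuretype == "exon":
                tid = feat.attributes["transcript_id"][0]
                exons.setdefault(tid, []).append((start0, end0))

    rows = []
    for tid, rec in transcripts.items():
        ex = sorted(exons.get(tid, [(rec["start"], rec["end"])]))
        lo, hi = min(s for s, _ in ex), max(e for _, e in ex)
        if lo < rec["start"] or hi > rec["end"]:
            warnings.warn(
                f"exon outside declared span for {tid}; span expanded",
                RuntimeWarning,
                stacklevel=2,
            )
            rec["start"], rec["end"] = min(lo, rec["start"]), max(hi, rec["end"])
        rec["exon_count"] = len(ex)
        rec["spliced_length"] = sum(e - s for s, e in ex)
        rows.append(rec)
    catalog = pd.DataFrame(
        rows,
        columns=["transcript_id", "gene_id", "chrom", "start", "end", "strand",
                 "exon_count", "spliced_length", "class_code"],
    )

    sequences: dict[str, str] = {}
    if fasta_path is not None:
        fasta = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
        for tid in catalog["transcript_id"]:
            if tid in fasta:
                sequences[tid] = fasta[tid]
            else:
                logger.warning("no FASTA record for transcript %s; sequence unset", tid)
        for extra in set(fasta) - set(catalog["transcript_id"]):
            logger.warning("FASTA record %s matches no transcript", extra)
    return catalog, sequences


def write_gtf(catalog: pd.DataFrame, path, exon_gap: int = 500) -> None:
    """Write transcript + exon GTF lines (1-based inclusive coordinates).

    Exon structure is synthesized from exon_count and spliced_length:
    equal-sized exons separated by ``exon_gap`` introns inside the span
    (exact per-exon structure is not tracked by the catalog).
    """
    with open(path, "w") as fh:
        for _, r in catalog.iterrows():
            attrs = (
                f'gene_id "{r["gene_id"]}"; transcript_id "{r["transcript_id"]}"; '
                f'class_code "{r["class_code"]}";'
            )
            fh.write(
                "\t".join(
                    [
                        str(r["chrom"]), "heterosiskit", "transcript",
                        str(int(r["start"]) + 1), str(int(r["end"])),
                        ".", r["strand"], ".", attrs,
                    ]
                )
                + "\n"
            )
            n_ex = int(r["exon_count"])
            total = int(r["spliced_length"])
            base = total // n_ex
            lengths = [base + (1 if i < total % n_ex else 0) for i in range(n_ex)]
            pos = int(r["start"])
            for ln in lengths:
                fh.write(
                    "\t".join(
                        [
                            str(r["chrom"]), "heterosiskit", "exon",
                            str(pos + 1), str(pos + ln),
                            ".", r["strand"], ".", attrs,
                        ]
                    )
                    + "\n"
                )
                pos += ln + exon_gap


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# config / manifest

def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def write_manifest(path, command: str, parameters: dict) -> None:
    """JSON run manifest: command, parameters, package version."""
    from heterosiskit import __version__

    manifest = {
        "command": command,
        "parameters": parameters,
        "heterosiskit_version": __version__,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
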