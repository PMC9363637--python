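#!/usr/bin/env python
"""Differential expression for the five standard contrasts.

Runs the NB-Wald test for P2 vs P1 and each cross against each parent, at
the headline criteria (adjusted p < 0.05 and |log2FC| > 1), and again with
the fold-change gate off (the calls that feed inheritance classification).
Writes per-contrast tables under results/de/ and results/de_classify/.
"""

from pathlib import Path

from heterosiskit import io as hio
from heterosiskit.de import run_standard_contrasts

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    counts, samples = hio.read_counts(
        BASE / "inputs" / "counts.tsv", BASE / "inputs" / "samples.tsv"
    )
    for sub, lfc_min in (("de", 1.0), ("de_classify", 0.0)):
        out = BASE / sub
        out.mkdir(parents=True, exist_ok=True)
        results = run_standard_contrasts(counts, samples, lfc_min=lfc_min)
        for name, table in results.items():
            table.to_csv(out / f"de_{name}.tsv", sep="\t", index=False)
        if lfc_min > 0:
            print(f"differential features at padj<0.05, |log2FC|>{lfc_min:g}:")
            for name, table in results.items():
                n_de = int((table["call"] != "ns").sum())
                print(f"  {name:12s}: {n_de}")


if __name__ == "__main__":
    main()
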