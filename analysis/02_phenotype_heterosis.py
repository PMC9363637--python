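#!/usr/bin/env python
"""Mid-parent heterosis of the maturation phenotypes, per trait and cross.

Reads the simulated phenotypes (planted H%: pubic space +25, oviduct length
+25, age at first egg -8) and reports H%, the one-sample t statistic against
the mid-parent value, and its two-sided p. Writes results/heterosis.tsv.
"""

from pathlib import Path

import pandas as pd

from heterosiskit import io as hio
from heterosiskit.heterosis import heterosis_test

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    pheno = hio.read_phenotypes(BASE / "inputs" / "phenotypes.tsv")
    rows = []
    for trait, sub in pheno.groupby("trait"):
        pm = sub.loc[sub["group"] == "P1", "value"].to_numpy()
        pf = sub.loc[sub["group"] == "P2", "value"].to_numpy()
        for cross in ("F1a", "F1b"):
            f1 = sub.loc[sub["group"] == cross, "value"].to_numpy()
            rows.append(vars(heterosis_test(f1, pm, pf, trait=trait, cross=cross)))
    table = pd.DataFrame(rows)
    table.to_csv(BASE / "heterosis.tsv", sep="\t", index=False)
    for _, r in table.iterrows():
        verdict = "significant" if r["p_value"] < 0.05 else "not significant"
        print(
            f"{r['trait']:>15} {r['cross']}: H% = {r['h_percent']:+6.2f} "
            f"(t = {r['t_stat']:+.2f}, df = {r['df']}, p = {r['p_value']:.2e}) "
            f"-> {verdict}"
        )


if __name__ == "__main__":
    main()
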