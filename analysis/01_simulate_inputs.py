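#!/usr/bin/env python
"""Generate every input for the downstream analyses, with planted truth.

Emulates the study design: two purebred groups (P1=WW, P2=YY) and the two
reciprocal crosses (F1a=WY, F1b=YW), six replicates each; per-individual
phenotypes for three maturation traits with planted mid-parent heterosis;
a transcript catalog with coding-potential scores and a known-lncRNA
reference. Writes everything under results/inputs/.
"""

from pathlib import Path

from heterosiskit import io as hio
from heterosiskit.simulate import (
    SimulationConfig,
    simulate_expression_experiment,
    simulate_phenotypes,
    simulate_transcript_set,
)

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    cfg = SimulationConfig(seed=SEED)  # 2000 features, 6 reps, fold 4
    counts, samples, truth = simulate_expression_experiment(cfg)
    hio.write_counts(counts, OUT / "counts.tsv")
    hio.write_sample_table(samples, OUT / "samples.tsv")
    truth.to_csv(OUT / "expression_truth.tsv", sep="\t", index=False)
    print(f"counts: {counts.shape[0]} features x {counts.shape[1]} samples")
    print("planted modes:", truth["mode"].value_counts().to_dict())

    pheno, pheno_truth = simulate_phenotypes(n_per_group=30, seed=SEED)
    hio.write_phenotypes(pheno, OUT / "phenotypes.tsv")
    pheno_truth.to_csv(OUT / "phenotype_truth.tsv", sep="\t", index=False)
    print("phenotypes:", pheno_truth.to_dict("records"))

    catalog, seqs, scores, reference, t_truth = simulate_transcript_set(
        n=400, seed=SEED
    )
    hio.write_gtf(catalog, OUT / "transcripts.gtf")
    hio.write_fasta(seqs, OUT / "transcripts.fa")
    hio.write_fasta(reference, OUT / "known_lncrnas.fa")
    hio.write_coding_scores(scores, OUT / "coding_scores.tsv")
    t_truth.to_csv(OUT / "transcript_truth.tsv", sep="\t", index=False)
    print(
        f"transcripts: {len(catalog)} "
        f"(known {int(t_truth['known'].sum())}, coding {int(t_truth['coding'].sum())})"
    )


if __name__ == "__main__":
    main()
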