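# heterosiskit

Analysis toolkit for **mid-parent heterosis in reciprocal-cross RNA-seq
designs**, modelled on studies of sexual-maturation heterosis in layer
chickens: two purebred lines (e.g. White Leghorn `WW` and Beijing You `YY`)
and their reciprocal F1 crosses (`WY`, `YW`) are phenotyped and profiled in
the ovary, and the hybrids' expression is decomposed into additive, dominant
and overdominant inheritance alongside an lncRNA catalog and co-expression
modules tied to maturation traits.

The package implements every computational layer of such a study and ships a
synthetic-data module that generates all inputs with planted ground truth, so
each stage has a recovery test with a known answer.

## What it computes

**Phenotype heterosis.** For a trait with F1 values `F1_i` (i = 1..N) and
parental means `P̄M`, `P̄F`:

    MP = (P̄M + P̄F) / 2
    H% = (F̄1 − MP) / MP × 100
    t  = (F̄1 − MP) / (s_F1 / √N),   df = N − 1   (two-sided p)

Positive H% means the hybrid exceeds the parental average; age at first egg
typically shows negative heterosis (earlier maturation). A `2^−ΔΔCt` qPCR
fold-change utility is included.

**Differential expression.** A self-contained negative-binomial Wald test on
counts: median-of-ratios size factors, per-gene method-of-moments dispersion
(Var = μ + αμ²) shrunk 50/50 toward a trimmed-mean prior, delta-method SE on
log2 fold change, Benjamini–Hochberg FDR. Headline DE calls use
padj < 0.05 and |log2FC| > 1.

**Inheritance classification.** Each feature's three directional calls —
P2 vs P1, F1 vs P1, F1 vs P2 — map to twelve bins (I–XII), grouped as
additivity {IV, X}, dominance {III, V, IX, XI} and overdominance
{I, II, VI, VII, VIII, XII}; all-ns is conserved and the 14 internally
inconsistent combinations are ambiguous. Nonadditive (dominant ∪
overdominant) sets are intersected across the reciprocal crosses.

**lncRNA catalog.** The identification cascade: spliced length ≥ 200 bp, a
definite strand, assembly class code in {i, u, x}; full-length sequence match
against a known-lncRNA reference ("known"); unanimous coding-potential
consensus (CNCI, CPC, PLEK < 0 plus a configurable Pfam E-value rule) for
"putative" lncRNAs; positional classes (intergenic/intronic/antisense) and
cis/trans target pairing by genomic distance (≤ 100 kb) and expression
correlation (|r| ≥ 0.9).

**Co-expression modules.** Unsigned weighted network |cor|^β (β auto-chosen
for scale-free fit), topological overlap, average-linkage clustering with a
simplified cut, module eigengenes (first PC of the standardized module), and
eigengene–trait Pearson correlation with Student-t p-values; top-1% edge
export for visualization.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic data
(seed 1; 2000 features, 6 replicates per group, parental fold 4):

```bash
python analysis/01_simulate_inputs.py
python analysis/02_phenotype_heterosis.py
```

prints, among others:

```
pubic_space F1a: H% = +24.40 (t = +13.26, df = 29, p = 7.73e-14) -> significant
        AFE F1a: H% =  -8.72 (t =  -6.56, df = 29, p = 3.51e-07) -> significant
```

— the planted +25% pubic-space heterosis and −8% AFE heterosis are recovered
with the right sign and magnitude. Continuing,

```bash
python analysis/03_differential_expression.py
python analysis/04_inheritance_patterns.py
```

```
F1a: 1469 features differential in >=1 contrast; nonadditive 69.43%
     (dominant 602, overdominant 418, additive 398)
shared nonadditive: 982; unique F1a 38, F1b 28
F1a: planted-pattern recovery 97.0%
```

97% of the 1400 non-conserved planted modes are recovered at pattern level.
`05_lncrna_catalog.py` and `06_coexpression_modules.py` finish the pipeline
(coding-label precision 1.000; module recovery ARI 0.995; module-3 eigengene
tracks the planted trait at r = +0.97). All tables land under `results/`.

A `heterosiskit` console script exposes the same stages as subcommands
(`simulate`, `heterosis`, `de`, `classify`, `lncrna`, `modules`, `report`)
with TSV outputs and a JSON run manifest per invocation.

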