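# Methods

## Study design emulated

The package targets a two-purebred / reciprocal-cross expression design:
four groups — parents P1 and P2 and the two cross directions F1a and F1b —
with a small number of biological replicates per group (default 6, matching
typical ovary RNA-seq cohorts), per-individual phenotypes for maturation
traits (pubic space, oviduct length, age at first egg), and a transcript
catalog destined for lncRNA identification. Because deposited raw reads and
per-individual phenotypes of any given study are not reproducible at desk
scale, all analyses here are validated on synthetic data with planted
ground truth; the generator's defaults are the study conditions, not tuning
knobs.

## Synthetic data

**Counts.** Negative binomial with mean μ and dispersion α, Var = μ + αμ²
(gamma–Poisson mixture; α = 0 degenerates to Poisson). Defaults: 2000
features, base mean 100, parental fold 4, dispersion 0.05 — moderate
biological variability for inbred lines. Each feature carries a planted
inheritance mode (default mix: 20% additive, 15% + 15% dominant toward
either parent, 10% + 10% overdominant up/down, 30% conserved; deterministic
rounding makes label marginals exact). Parent orientation is randomized;
F1 means follow the mode: mid-parent (additive), the matched parent
(dominant), one extra fold beyond the extreme parent (overdominant), all
equal (conserved). Both crosses share the planted mode, so reciprocal
summaries have a known answer.

**Phenotypes.** Individuals ~ Normal(group mean, CV·mean), CV 0.1; both F1
group means are midparent·(1 + H/100), directly inverting the heterosis
estimator. Within-group phenotype variance is a free parameter of the
generator, not an estimate of any real population. Default planted H%:
+25 (pubic space), +25 (oviduct length), −8 (age at first egg — hybrids
mature earlier).

**Transcripts.** Log-normal spliced lengths (median ~1 kb, ~5% below the
200 bp cutoff), a 10% unstranded fraction, class codes over
{i, u, x, j, =, c}. "Known" transcripts have their sequence copied verbatim
into the reference FASTA. Coding transcripts draw CNCI/CPC/PLEK scores from
Normal(+3, 1) and Pfam E-values below 1e-5; noncoding from Normal(−3, 1)
with large E-values. Separation 3 was chosen a priori so each score falls
on the correct side with probability Φ(3) ≈ 0.9987, i.e. "well separated"
(triple-consensus recall ≈ 0.996).

**Modules.** A factor model: each planted module has a latent N(0, 1)
per-sample factor; member genes are loading·factor + N(0, noise_sd) with
loadings U(0.5, 1.5) and random sign (an unsigned network treats both
orientations alike); the trait is module 1's factor plus N(0, 0.2).

What the generator does **not** emulate: library-size composition bias
beyond a global scale, GC/length effects, batch structure, outlier
dispersion genes, transcript assembly artifacts, or realistic genomic
feature density. Passing recovery tests therefore demonstrates correctness
of the statistics under their own model assumptions, not robustness to
every artifact of real RNA-seq.

## Heterosis statistic

H% = (F̄1 − MP)/MP × 100 with MP the mid-parent value. Significance uses
t = (F̄1 − MP)/(s_F1/√N), df = N − 1, two-sided — parental means treated as
fixed constants, so only F1 dispersion enters. This delta-method form is
scale invariant and antisymmetric about the mid-parent, and its empirical
size is nominal (measured 0.045–0.056 at α = 0.05 across seeds). The
heterosis t formula as commonly printed in the crossbreeding literature is
typographically garbled and dimensionally inconsistent (its denominator
mixes a scale with a squared scale); a literal token-order transcription of
that printed form is available behind
`method="literal"` for comparison — it is sign-consistent with the default
but not endorsed. Degenerate inputs: zero F1 variance at the mid-parent
gives t = 0, p = 1; away from it the p-value underflows and is reported as
the machine minimum with an explicit flag; a zero mid-parent is an error
(H% undefined).

## Differential expression

A deliberately small NB-Wald test rather than a DESeq2 clone (no trended
dispersion fit, no LFC shrinkage, no independent filtering), so that every
step is checkable by hand and the inheritance layer is self-contained:

* **Normalization** — median-of-ratios over features positive in every
  sample, factors rescaled to geometric mean 1; upper-quartile fallback
  (with a warning) when no such feature exists.
* **Dispersion** — per-gene method of moments (v − m)/m² pooled across the
  two groups (df-weighted), floored at 1e-8, shrunk 50/50 toward the
  20%-trimmed mean across genes. The shrinkage stabilizes the n = 6 moment
  estimate enough for near-nominal calibration (measured null rejection
  0.063–0.065 at α = 0.05, dispersion 0.1).
* **Test** — log2FC of normalized group means (0.5 pseudocount added to
  both means when either is zero, preserving swap symmetry), delta-method
  SE √((1+αm_a)/(n_a m_a) + (1+αm_b)/(n_b m_b))/ln 2, two-sided normal p,
  Benjamini–Hochberg step-up (implemented directly; verified against both a
  brute-force evaluation and statsmodels).

"Adjusted P" is interpreted as BH FDR, the de facto standard. Headline
DEG/DEL calls use padj < 0.05 **and** |log2FC| > 1.

**Thresholds for classification.** The three contrasts feeding inheritance
classification use directional significance alone (lfc_min = 0). This is a
deliberate design choice: with parents 4-fold apart, an additive feature's
mid-parent mean lies only log2(2.5/4) ≈ −0.68 below the high parent, so a
uniform |log2FC| > 1 gate can never produce the "below the high parent"
call and additivity would be structurally unrecoverable. The fold gate
remains the definition of the headline DE universe; the run manifest
records both thresholds.

## Inheritance classification

The 27 combinations of three calls map deterministically to twelve bins,
conserved, or ambiguous; the bin → pattern grouping is additivity {IV, X},
dominance {III, V, IX, XI}, overdominance {I, II, VI, VII, VIII, XII}.
Additivity requires significance against **both** parents with opposite
directions (strictly between). Relabelling the parents permutes bins as
(II XII)(III XI)(IV X)(V IX)(VI VIII), fixing I and VII, and preserves every
pattern — a symmetry the tests verify exhaustively. Summaries report
pattern proportions over the features differential in at least one of the
three contrasts for that cross, and nonadditive sets are intersected across
crosses by feature id.

## lncRNA cascade

Three pure refinement stages (basic filter → known matching → coding
consensus), each recording a rejection reason. Boundary readings are
strict and literal: length exactly 200 passes ("less than 200 removed"),
score exactly 0 fails (< 0 required), E-value exactly 1e-5 fails the
as-printed rule. "Perfectly aligned" is read as exact full-length identity
by default; `identity_min` relaxes it (same-length, ungapped, position-wise
identity with a prefix prefilter). The printed Pfam criterion
(E-value < 1e-5) demands a confident protein-domain **hit**, which likely
inverts the intended "no coding evidence" rule; both readings are
implemented (`as_printed`, the default, and `no_hit_required`) and the
choice is logged in the manifest. Recovery analyses use `no_hit_required`,
the biologically coherent reading. Positional classes come from the class
code (u/i/x → intergenic/intronic/antisense) with a coordinate fallback for
'.' codes. Distances use 0-based half-open spans, gap 0 for overlap and ∞
across chromosomes; cis requires the same chromosome within 100 kb, and
pairing requires |Pearson r| ≥ 0.9 on log2(normalized + 1) expression.
The 100 kb / 0.9 defaults are conventional values, exposed as flags.

## Co-expression network

Expression is log2(normalized + 1); the top 40% most-variant features are
kept (ceiling, ties broken by feature id). Unsigned adjacency |cor|^β with
β the smallest power in 1..20 whose connectivity distribution fits a
scale-free law at R² ≥ 0.8 (fallback 6 with a warning). Topological
overlap TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i, k_j) + 1 − a_ij).

**Module detection** replaces the dynamic hybrid tree cut with a simplified,
recovery-tested procedure: average-linkage clustering of 1 − TOM, a static
cut at the 0.99 quantile of merge heights, removal of clusters below
min_module_size (50), a cohesion screen, and iterative eigengene merging
while any two module eigengenes correlate above 1 − mergeCutHeight (0.25).
The cohesion screen keeps a cluster only when its mean within-cluster |r|
exceeds twice the independence-null expectation E|r| ≈ √(2/π)/√(n − 1);
without it, average linkage on an unstructured matrix yields one giant
spurious cluster (measured: noise clusters reach mean |r| ≤ 0.21 at n = 24
versus ≥ 0.57 for planted modules, against a threshold of 0.33). A weak but
genuine module whose mean |r| falls below that threshold would be dropped —
a known limitation of the screen.

Eigengenes are the leading right-singular direction of the standardized
module submatrix, unit variance, sign-oriented to correlate positively with
members on average; module–trait association uses Pearson r with
t = r√(n−2)/√(1−r²) on n − 2 df. Top-edge export ranks within-module pairs
by |r| and keeps the top 1% (ceiling, at least one edge per module);
a global scope is available behind a flag since the selection scope is a
presentation choice.

## Numerical and interface choices

Internal coordinates are 0-based half-open, converted at the GTF boundary
(1-based inclusive). Readers reject rather than coerce (non-integer counts,
duplicate ids, negative E-values, unmapped group labels); group labels map
through a configurable alias table (WW/YY/WY/YW → P1/P2/F1a/F1b by default)
so any purebred/cross naming works. All stages are deterministic given a
seed; writers and readers round-trip losslessly. Problem sizes in the
analysis drivers and acceptance script (2000 features × 24 samples, 300-gene
module fixture, 400-transcript catalog, 500–2000 replicate calibrations)
were chosen as the smallest sizes at which the calibration and recovery
properties are measured stably.

## Known limitations

* The DE test's Wald normal approximation is slightly anticonservative at
  very small n; calibration was verified at n = 6 per group only.
* The simplified tree cut does not reproduce dynamicTreeCut module
  boundaries or labels; only recovery of well-separated structure is
  claimed.
* Known-lncRNA matching is forward-strand, full-length; it is not a local
  aligner.
* cis/trans pairing is a screen on distance and correlation, not a causal
  inference.
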