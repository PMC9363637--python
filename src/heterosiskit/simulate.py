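"""Synthetic data with planted ground truth.

Every downstream stage of the pipeline (heterosis test, differential
expression, inheritance classification, lncRNA cascade, co-expression
modules) is exercised against fixtures produced here, so each has a
recovery test with a known answer.

The expression generator emulates a two-purebred / reciprocal-cross design:
four groups (P1, P2 and the two F1 directions F1a, F1b) with a small number
of biological replicates each, negative-binomial counts, and a per-feature
planted inheritance mode. The NB is parameterized by mean ``mu`` and
dispersion ``alpha`` with ``Var = mu + alpha * mu**2``; ``alpha = 0``
degenerates to Poisson.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("P1", "P2", "F1a", "F1b")
#: conventional breed-style aliases for the four groups (sire listed first)
GROUP_ALIASES = {"WW": "P1", "YY": "P2", "WY": "F1a", "YW": "F1b"}

MODES = (
    "additive",
    "dominant_P1",
    "dominant_P2",
    "overdominant_up",
    "overdominant_down",
    "conserved",
)

_DEFAULT_MODE_FRACTIONS = {
    "additive": 0.20,
    "dominant_P1": 0.15,
    "dominant_P2": 0.15,
    "overdominant_up": 0.10,
    "overdominant_down": 0.10,
    "conserved": 0.30,
}


@dataclass
class SimulationConfig:
    """Parameters of the planted expression experiment.

    ``fold_change`` is the ratio between the two parental means for every
    non-conserved feature; overdominant features are placed one further
    fold beyond the extreme parent so the planted signal is unambiguous.
    """

    n_features: int = 2000
    n_replicates: int = 6
    mode_fractions: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MODE_FRACTIONS)
    )
    base_mean: float = 100.0
    fold_change: float = 4.0
    dispersion: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        unknown = set(self.mode_fractions) - set(MODES)
        if unknown:
            raise ValueError(f"unknown inheritance modes: {sorted(unknown)}")
        total = sum(self.mode_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mode_fractions must sum to 1, got {total!r}")
        if any(f < 0 for f in self.mode_fractions.values()):
            raise ValueError("mode_fractions must be non-negative")
        if not math.isfinite(self.base_mean) or self.base_mean <= 0:
            raise ValueError("base_mean must be positive and finite")
        if self.fold_change <= 1:
            raise ValueError("fold_change must be > 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mu, alpha) draws via the gamma-Poisson mixture; Poisson at alpha=0."""
    mu = np.asarray(mu, dtype=float)
    if not np.all(np.isfinite(mu)):
        raise ValueError("non-finite NB means")
    if alpha < 0:
        raise ValueError("dispersion must be >= 0")
    if alpha == 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
    return rng.poisson(lam)


def _rounded_mode_counts(fractions: dict[str, float], n: int) -> dict[str, int]:
    # cumulative rounding: totals are deterministic and sum exactly to n
    counts: dict[str, int] = {}
    cum = 0.0
    assigned = 0
    for mode in MODES:
        cum += fractions.get(mode, 0.0)
        upto = int(round(cum * n))
        counts[mode] = upto - assigned
        assigned = upto
    counts[MODES[-1]] += n - assigned
    return counts


def simulate_expression_experiment(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the four-group count matrix with planted inheritance modes.

    Returns ``(counts, samples, truth)``:

    * ``counts`` — integer DataFrame, features × samples;
    * ``samples`` — sample table with columns ``sample_id`` and ``group``
      (canonical labels P1/P2/F1a/F1b);
    * ``truth`` — per feature: the planted mode and the four group means.

    Group means: the two parents sit ``fold_change`` apart (orientation
    randomized per feature); F1 means follow the planted mode — mid-parent
    for additive, the matched parent for dominant, one fold beyond the
    extreme parent for overdominant, all equal for conserved. Both crosses
    share the same planted mode and mean.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_features
    fc = config.fold_change
    base = config.base_mean

    mode_counts = _rounded_mode_counts(config.mode_fractions, n)
    modes = np.concatenate(
        [np.repeat(m, c) for m, c in mode_counts.items()]
    )

    # orientation: which parent carries the high mean (non-conserved only)
    p1_high = rng.random(n) < 0.5
    mu_p1 = np.where(p1_high, base * fc, base)
    mu_p2 = np.where(p1_high, base, base * fc)
    conserved = modes == "conserved"
    mu_p1 = np.where(conserved, base, mu_p1)
    mu_p2 = np.where(conserved, base, mu_p2)

    mu_f1 = np.empty(n)
    mid = (mu_p1 + mu_p2) / 2.0
    hi = np.maximum(mu_p1, mu_p2)
    lo = np.minimum(mu_p1, mu_p2)
    mu_f1[modes == "additive"] = mid[modes == "additive"]
    mu_f1[modes == "dominant_P1"] = mu_p1[modes == "dominant_P1"]
    mu_f1[modes == "dominant_P2"] = mu_p2[modes == "dominant_P2"]
    mu_f1[modes == "overdominant_up"] = (hi * fc)[modes == "overdominant_up"]
    mu_f1[modes == "overdominant_down"] = (lo / fc)[modes == "overdominant_down"]
    mu_f1[conserved] = base

    group_mu = {"P1": mu_p1, "P2": mu_p2, "F1a": mu_f1, "F1b": mu_f1}
    alias_of = {v: k for k, v in GROUP_ALIASES.items()}

    feature_ids = [f"feat_{i:05d}" for i in range(n)]
    cols: dict[str, np.ndarray] = {}
    sample_rows = []
    for group in GROUPS:
        for r in range(config.n_replicates):
            sid = f"{alias_of[group]}_{r + 1}"
            cols[sid] = _nb_counts(rng, group_mu[group], config.dispersion)
            sample_rows.append({"sample_id": sid, "group": group})

    counts = pd.DataFrame(cols, index=pd.Index(feature_ids, name="feature_id"))
    samples = pd.DataFrame(sample_rows)
    truth = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "mode": modes,
            "mu_P1": mu_p1,
            "mu_P2": mu_p2,
            "mu_F1": mu_f1,
        }
    )
    return counts, samples, truth


# ---------------------------------------------------------------------------
# phenotypes

_DEFAULT_TRAITS = {
    # trait: (P1 mean, P2 mean, planted H%)
    "pubic_space": (28.0, 40.0, 25.0),       # mm
    "oviduct_length": (550.0, 450.0, 25.0),  # mm
    "AFE": (150.0, 170.0, -8.0),             # days; hybrids mature earlier
}


def simulate_phenotypes(
    n_per_group: int = 30,
    traits: dict[str, tuple[float, float, float]] | None = None,
    cv: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-individual phenotypes with a planted mid-parent heterosis.

    Individuals are drawn Normal(group mean, cv * group mean); both F1
    group means equal ``midparent * (1 + H_planted / 100)``, directly
    inverting the heterosis estimator. Returns ``(phenotypes, truth)``
    where phenotypes has columns individual_id, group, trait, value.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    traits = dict(_DEFAULT_TRAITS) if traits is None else traits
    rng = np.random.default_rng(seed)
    alias_of = {v: k for k, v in GROUP_ALIASES.items()}

    rows = []
    truth_rows = []
    for trait, (m1, m2, h) in traits.items():
        mid = (m1 + m2) / 2.0
        f1_mean = mid * (1.0 + h / 100.0)
        means = {"P1": m1, "P2": m2, "F1a": f1_mean, "F1b": f1_mean}
        truth_rows.append({"trait": trait, "planted_h_percent": h,
                           "midparent": mid, "f1_mean": f1_mean})
        for group in GROUPS:
            mu = means[group]
            values = rng.normal(mu, cv * abs(mu), size=n_per_group)
            for i, v in enumerate(values):
                rows.append(
                    {
                        "individual_id": f"{alias_of[group]}_{i + 1}",
                        "group": group,
                        "trait": trait,
                        "value": float(v),
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# transcript catalog / coding scores

_CLASS_CODES = ("i", "u", "x", "j", "=", "c")
_CLASS_CODE_P = (0.16, 0.28, 0.12, 0.16, 0.18, 0.10)
_BASES = np.array(list("ACGT"))


def simulate_transcript_set(
    n: int,
    seed: int = 0,
    known_fraction: float = 0.3,
    coding_fraction: float = 0.4,
    unstranded_fraction: float = 0.1,
    score_separation: float = 3.0,
) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame, dict[str, str], pd.DataFrame]:
    """Transcript records, sequences, coding scores and a reference set.

    Returns ``(catalog, sequences, scores, reference, truth)``. Lengths are
    log-normal (a small tail falls below 200 bp), a configured fraction of
    transcripts is unstranded, and class codes span assembled-vs-annotation
    categories {i, u, x, j, =, c}. "Known" transcripts have their sequence
    copied verbatim into the reference FASTA dict. Coding transcripts draw
    CNCI/CPC/PLEK scores from Normal(+separation, 1) and Pfam E-values
    below 1e-5 (a real protein-domain hit); noncoding transcripts draw from
    Normal(-separation, 1) with large E-values.
    """
    for name, f in (
        ("known_fraction", known_fraction),
        ("coding_fraction", coding_fraction),
        ("unstranded_fraction", unstranded_fraction),
    ):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    empty = pd.DataFrame(
        columns=["transcript_id", "gene_id", "chrom", "start", "end",
                 "strand", "exon_count", "spliced_length", "class_code"]
    )
    if n == 0:
        scores = pd.DataFrame(
            columns=["transcript_id", "cnci", "cpc", "plek", "pfam_evalue"]
        )
        truth = pd.DataFrame(columns=["transcript_id", "coding", "known"])
        return empty, {}, scores, {}, truth

    rng = np.random.default_rng(seed)
    lengths = np.maximum(
        50, rng.lognormal(mean=math.log(1000.0), sigma=1.0, size=n)
    ).astype(int)
    unstranded = rng.random(n) < unstranded_fraction
    strands = np.where(unstranded, ".", np.where(rng.random(n) < 0.5, "+", "-"))
    codes = rng.choice(_CLASS_CODES, size=n, p=_CLASS_CODE_P)
    coding = rng.random(n) < coding_fraction
    known = rng.random(n) < known_fraction
    exon_counts = 1 + rng.poisson(1.2, size=n)
    chroms = rng.choice([f"chr{c}" for c in (1, 2, 3, 4, 5, "Z")], size=n)
    starts = rng.integers(1_000, 5_000_000, size=n)

    sequences: dict[str, str] = {}
    reference: dict[str, str] = {}
    rows = []
    truth_rows = []
    for i in range(n):
        tid = f"MSTRG.{i + 1}.1"
        seq = "".join(rng.choice(_BASES, size=int(lengths[i])))
        sequences[tid] = seq
        if known[i]:
            reference[f"ref_lnc_{i + 1}"] = seq
        # genomic span: spliced length spread over exons with intron gaps
        gaps = int(exon_counts[i] - 1) * 500
        rows.append(
            {
                "transcript_id": tid,
                "gene_id": f"MSTRG.{i + 1}",
                "chrom": chroms[i],
                "start": int(starts[i]),
                "end": int(starts[i] + lengths[i] + gaps),
                "strand": strands[i],
                "exon_count": int(exon_counts[i]),
                "spliced_length": int(lengths[i]),
                "class_code": codes[i],
            }
        )
        truth_rows.append(
            {"transcript_id": tid, "coding": bool(coding[i]), "known": bool(known[i])}
        )

    shift = score_separation
    sgn = np.where(coding, 1.0, -1.0)
    scores = pd.DataFrame(
        {
            "transcript_id": [r["transcript_id"] for r in rows],
            "cnci": rng.normal(sgn * shift, 1.0),
            "cpc": rng.normal(sgn * shift, 1.0),
            "plek": rng.normal(sgn * shift, 1.0),
            "pfam_evalue": np.where(
                coding,
                10.0 ** rng.uniform(-30, -6, size=n),
                10.0 ** rng.uniform(-4, 2, size=n),
            ),
        }
    )
    catalog = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return catalog, sequences, scores, reference, truth


# ---------------------------------------------------------------------------
# block-structured co-expression

def simulate_module_structure(
    n_genes: int = 300,
    n_samples: int = 24,
    n_modules: int = 3,
    noise_sd: float = 0.5,
    seed: int = 0,
    trait_noise_sd: float = 0.2,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Factor-model expression with planted modules and a module-driven trait.

    Each module has a latent per-sample factor ~ N(0, 1); a member gene is
    ``loading * factor + N(0, noise_sd)`` with loadings U(0.5, 1.5) and a
    random sign (an unsigned network treats both orientations alike). The
    trait is module 1's factor plus N(0, trait_noise_sd). Returns
    ``(expression, trait, truth)`` with expression features × samples.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if trait_noise_sd < 0:
        raise ValueError("trait_noise_sd must be >= 0")
    if n_modules < 1:
        raise ValueError("n_modules must be >= 1")
    if n_genes % n_modules:
        raise ValueError("n_genes must divide evenly across modules")

    rng = np.random.default_rng(seed)
    per = n_genes // n_modules
    factors = rng.normal(size=(n_modules, n_samples))
    sample_ids = [f"S{j + 1}" for j in range(n_samples)]

    data = np.empty((n_genes, n_samples))
    membership = np.repeat(np.arange(1, n_modules + 1), per)
    loadings = rng.uniform(0.5, 1.5, size=n_genes) * rng.choice(
        [-1.0, 1.0], size=n_genes
    )
    for g in range(n_genes):
        f = factors[membership[g] - 1]
        data[g] = loadings[g] * f + rng.normal(0.0, noise_sd, size=n_samples)

    gene_ids = [f"gene_{g:04d}" for g in range(n_genes)]
    expr = pd.DataFrame(data, index=pd.Index(gene_ids, name="feature_id"),
                        columns=sample_ids)
    trait = pd.Series(
        factors[0] + rng.normal(0.0, trait_noise_sd, size=n_samples),
        index=sample_ids,
        name="trait",
    )
    truth = pd.DataFrame({"feature_id": gene_ids, "module": membership,
                          "loading": loadings})
    return expr, trait, truth
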