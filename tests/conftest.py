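import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from heterosiskit.simulate import (
    SimulationConfig,
    simulate_expression_experiment,
    simulate_module_structure,
    simulate_transcript_set,
)


@pytest.fixture(scope="session")
def standard_experiment():
    """The standard planted expression fixture: 2000 features, 6 reps/group,
    parental fold 4, dispersion 0.05, seed 1."""
    cfg = SimulationConfig(
        n_features=2000, n_replicates=6, fold_change=4.0, dispersion=0.05, seed=1
    )
    return simulate_expression_experiment(cfg)


@pytest.fixture(scope="session")
def module_fixture():
    """Planted 3-module factor structure: 300 genes, 24 samples, noise 0.5."""
    return simulate_module_structure(
        n_genes=300, n_samples=24, n_modules=3, noise_sd=0.5, seed=7
    )


@pytest.fixture(scope="session")
def transcript_fixture():
    """400 synthetic transcripts with well-separated coding scores."""
    return simulate_transcript_set(n=400, seed=11)


def nb_counts(rng, mu, alpha, size):
    """Independent NB(mu, alpha) helper for ad-hoc simulations in tests."""
    mu = np.broadcast_to(np.asarray(mu, dtype=float), size)
    if alpha == 0:
        return rng.poisson(mu)
    lam = rng.gamma(1.0 / alpha, mu * alpha)
    return rng.poisson(lam)


def two_group_counts(rng, mu_a, mu_b, alpha, n_features, n_reps=6):
    """Count matrix + sample table for an A/B design."""
    cols = {}
    rows = []
    for g, mu in (("A", mu_a), ("B", mu_b)):
        for i in range(n_reps):
            sid = f"{g}_{i + 1}"
            cols[sid] = nb_counts(rng, mu, alpha, (n_features,))
            rows.append({"sample_id": sid, "group": g})
    counts = pd.DataFrame(cols, index=[f"f{i:05d}" for i in range(n_features)])
    counts.index.name = "feature_id"
    return counts, pd.DataFrame(rows)
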