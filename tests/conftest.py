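import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from staarlite.io import GenotypeBlock
from staarlite.null_model import fit_null_model, score_statistics

settings.register_profile(
    "det", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("det")


def make_logistic_pheno(n, seed, beta0=0.2, beta_x=0.8):
    """Simple covariate-driven binary phenotype table."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    p = 1.0 / (1.0 + np.exp(-(beta0 + beta_x * x)))
    y = rng.binomial(1, p)
    return pd.DataFrame(
        {"sample_id": [f"S{i:05d}" for i in range(n)], "outcome": y, "x": x}
    )


def block_from_columns(cols, samples=None, gene=None):
    """GenotypeBlock from a list of dosage columns (one per variant)."""
    cols = [np.asarray(c, dtype=float) for c in cols]
    n, m = len(cols[0]), len(cols)
    variants = pd.DataFrame(
        {"chrom": "1", "pos": 100 + 10 * np.arange(m), "ref": "A", "alt": "T"}
    )
    if gene is not None:
        variants["gene"] = gene
    if samples is None:
        samples = np.array([f"S{i:05d}" for i in range(n)])
    return GenotypeBlock(samples, np.column_stack(cols), variants)


@pytest.fixture(scope="session")
def null_model_300():
    """Fitted logistic null model on 300 samples, with its phenotype table."""
    pheno = make_logistic_pheno(300, seed=123)
    model = fit_null_model(pheno, ["x"])
    return model, pheno


@pytest.fixture(scope="session")
def random_score_stats(null_model_300):
    """Score statistics for 6 random rare variants under the 300-sample null."""
    model, _ = null_model_300
    rng = np.random.default_rng(99)
    G = rng.binomial(2, rng.uniform(0.005, 0.05, size=6), size=(300, 6)).astype(float)
    # ensure polymorphic
    G[0, G.sum(0) == 0] = 1.0
    return score_statistics(model, G), G
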