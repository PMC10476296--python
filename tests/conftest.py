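import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from burdenblend.io_formats import GenotypeMatrix
from burdenblend.synthetic_data import SimulationConfig, pick_causal_genes, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic 800-sample cohort with two signed gene effects and a
    modest polygenic component, shared by read-only tests."""
    cfg = SimulationConfig(
        n_samples=800,
        n_genes=30,
        n_common_snps=80,
        causal_genes=pick_causal_genes(30, [0.6, -0.5]),
        n_causal_snps=15,
        snp_effect_sd=0.15,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_genotypes(rng, n_samples=5, n_variants=8, missing_rate=0.0):
    d = rng.integers(0, 3, size=(n_samples, n_variants)).astype(np.int16)
    if missing_rate:
        d[rng.random(d.shape) < missing_rate] = -1
    return GenotypeMatrix(
        np.array([f"S{i}" for i in range(n_samples)], dtype=object),
        np.array([f"v{j}" for j in range(n_variants)], dtype=object),
        d,
    )


@pytest.fixture()
def covariates_frame(rng):
    n = 200
    return pd.DataFrame(
        {
            "bmi": rng.normal(27, 4, n),
            "age": rng.normal(55, 8, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "pc1": rng.normal(0, 1, n),
            "pc2": rng.normal(0, 1, n),
            "pc3": rng.normal(0, 1, n),
            "pc4": rng.normal(0, 1, n),
        },
        index=[f"S{i}" for i in range(n)],
    )
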