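import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import saeindex as sx

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def fast_config(seed: int, **overrides) -> sx.SimulationConfig:
    """Reduced-size cohort for unit tests (full sizes live in acceptance)."""
    base = dict(n_genes=400, n_responsive=50, n_nonsmoker=24, n_smoker=30,
                n_copd=12, seed=seed)
    base.update(overrides)
    return sx.SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """One small synthetic cohort shared by read-only tests."""
    cfg = fast_config(seed=11)
    m, pheno, truth = sx.generate_cohort(cfg)
    return cfg, sx.normalize_per_chip(m), pheno, truth


@pytest.fixture(scope="session")
def small_signature(small_cohort):
    cfg, m, pheno, truth = small_cohort
    sig = sx.select_signature(m, pheno, truth.annotation)
    return sig


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def toy_matrix(values, probes=None, samples=None, normalized=False, calls=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    vdf = pd.DataFrame(values, index=pd.Index(probes, name="probe_id"),
                       columns=pd.Index(samples, name="sample_id"))
    cdf = None
    if calls is not None:
        cdf = pd.DataFrame(np.asarray(calls), index=vdf.index, columns=vdf.columns)
    return sx.ExpressionMatrix(values=vdf, calls=cdf, normalized=normalized)
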