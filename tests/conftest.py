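import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from litterlink.config import PipelineConfig
from litterlink.synthetic import SimConfig, generate_synthetic_study

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_study():
    """Full default twin-litter study, seed 1 (three tissues)."""
    return generate_synthetic_study(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_study():
    """A scaled-down study for fast pipeline-level tests."""
    cfg = SimConfig(
        n_genes=400,
        n_features=120,
        n_driver_features=2,
        genes_per_driver=20,
        n_gene_sets=40,
        enriched_sets_per_driver=8,
        n_background_de_genes=30,
        sex_effect_genes=10,
        n_discordant_pairs=6,
        tissues=("intestine",),
        seed=7,
    )
    return cfg, generate_synthetic_study(cfg)


@pytest.fixture()
def pipeline_config():
    return PipelineConfig(seed=11, n_perm=199)
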