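import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from faerspv import faers_io
from faerspv.synthetic import GeneratorConfig, generate

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_dataset():
    """A 300-report synthetic dataset with one planted association."""
    config = GeneratorConfig(
        n_reports=300,
        n_drugs=8,
        n_pts=20,
        n_socs=4,
        target_ps_rate=0.2,
        planted_signals=(("TRAZODONE", "PT_0005", 12.0),),
        seed=11,
    )
    return generate(config)


@pytest.fixture(scope="session")
def small_cases(small_dataset):
    demo = faers_io.deduplicate_cases(small_dataset.demo)
    return faers_io.assemble_cases(
        demo,
        small_dataset.drug,
        small_dataset.reac,
        small_dataset.outc,
        small_dataset.ther,
        small_dataset.indi,
    )


@pytest.fixture(scope="session")
def target_ids(small_cases):
    kept = faers_io.filter_primary_suspect(small_cases, ["trazodone"])
    return {c.primary_id for c in kept}


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
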