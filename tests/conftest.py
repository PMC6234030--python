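import pytest

from glomquant import (
    GlomerulusDataset,
    SpatialConfig,
    SynthConfig,
    expand_contacts,
    generate_glomerulus,
)


def small_config(seed: int = 7, **overrides) -> SynthConfig:
    """A scaled-down glomerulus: same structure, ~1/10 the synapse count."""
    defaults = dict(
        census={
            "ORN_ipsi": 8,
            "ORN_contra": 9,
            "PN": 4,
            "LN": 9,
            "other": 2,
            "orphan": 2,
        },
        n_tbars=1200,
        minor_tbar_mean=12.0,
        neuropile_volume_um3=500.0,
        seed=seed,
    )
    defaults.update(overrides)
    return SynthConfig(**defaults)


@pytest.fixture(scope="session")
def study_dataset():
    """One study-scale synthetic glomerulus, shared across tests."""
    dataset, truth = generate_glomerulus(SynthConfig(seed=7))
    return dataset, truth


@pytest.fixture(scope="session")
def study_contacts(study_dataset):
    dataset, _ = study_dataset
    return expand_contacts(dataset)


@pytest.fixture()
def small_dataset():
    dataset, truth = generate_glomerulus(small_config())
    return dataset, truth
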