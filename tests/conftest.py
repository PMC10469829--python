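import dataclasses

import pytest

from svybias import ModelSpec, SimConfig, draw_two_stage_sample, generate_population


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A small but non-degenerate survey: 80 clusters of 60 children."""
    return SimConfig(
        n_clusters_total=80,
        children_per_cluster=60,
        sampled_clusters=40,
        children_sampled_per_cluster={"urban": 10, "rural": 15},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_survey(small_config):
    pop = generate_population(small_config)
    sample, clusters = draw_two_stage_sample(pop, small_config)
    return pop, sample, clusters


@pytest.fixture(scope="session")
def default_spec() -> ModelSpec:
    return ModelSpec(
        covariates={"sex": ("male", "female"), "residence": ("urban", "rural")}
    )


@pytest.fixture(scope="session")
def weighted_spec(default_spec) -> ModelSpec:
    return dataclasses.replace(default_spec, weighting="pseudo_likelihood")
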