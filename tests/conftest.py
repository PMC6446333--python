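import pytest
from hypothesis import HealthCheck, settings

from subchrom import (
    SampleSpec,
    SimulationConfig,
    simulate_genotypes,
    simulate_marker_map,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def small_config(seed: int = 7, **overrides) -> SimulationConfig:
    """A 3-chromosome cohort small enough for every unit test."""
    base = dict(
        chromosome_lengths={"4A": 40_000_000, "4B": 50_000_000, "4D": 30_000_000},
        n_markers=3_000,
        samples=(
            SampleSpec("P1", "wheat_parent"),
            SampleSpec("P2", "wheat_parent"),
            SampleSpec("ALIEN", "alien_donor"),
            SampleSpec("SubL1", "substitution_line", "4B"),
            SampleSpec("SubL2", "substitution_line", "4B"),
            SampleSpec("SubL3", "substitution_line", "4B"),
            SampleSpec("N1", "no_alien_derivative"),
        ),
        divergent_chromosomes={"4D": 0.08},
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def cohort():
    """(config, marker_map, genotypes, truth) for the standard small cohort."""
    config = small_config()
    marker_map = simulate_marker_map(config)
    genotypes, truth = simulate_genotypes(marker_map, config)
    return config, marker_map, genotypes, truth
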