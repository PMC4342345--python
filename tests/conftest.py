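import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import permeascape as ps

settings.register_profile(
    "suite", max_examples=25, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def fig2_sites():
    """Three-population toy geometry: a close pair of populations with a
    distant third, mirroring the diagrammed segment-selection rules."""
    coords = {
        "a1": (0.0, 0.0), "a2": (0.0, 1000.0), "a3": (0.0, 2000.0),
        "b1": (600.0, 0.0), "b2": (600.0, 1000.0),
        "c1": (5000.0, 0.0),
    }
    sites = [ps.SampleSite(id=k, x=x, y=y) for k, (x, y) in coords.items()]
    partition = ps.PopulationPartition(
        k=3,
        site_to_pop={"a1": 1, "a2": 1, "a3": 1, "b1": 2, "b2": 2, "c1": 3},
    )
    return sites, partition


@pytest.fixture(scope="session")
def small_scenario():
    cfg = ps.ScenarioConfig(
        seed=11, cell_side=2400.0, k_true=2, n_sites=16,
        individuals_per_site=4, theta_drift=0.15,
        effect_coefficients={"forest": 2.5, "grassland": 8.5}, noise_sd=0.2,
    )
    return ps.generate_scenario(cfg)


@pytest.fixture(scope="session")
def segment_dataset():
    """70-segment dataset with known forest/grassland effects."""
    df = ps.simulate_segment_dataset(n_segments=70, seed=5)
    return df.assign(width=3.0)


def two_pop_partition(n_per_pop: int) -> ps.PopulationPartition:
    ind = {f"i{j:04d}": (1 if j < n_per_pop else 2) for j in range(2 * n_per_pop)}
    return ps.PopulationPartition(k=2, site_to_pop={}, individual_to_pop=ind)
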