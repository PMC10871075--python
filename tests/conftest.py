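import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from wavecnv.signal_io import MarkerMap, SignalSample
from wavecnv.synthetic import SimulationConfig, simulate_cohort
from wavecnv.wave_reference import build_reference


@pytest.fixture(scope="session")
def small_cfg():
    """Scaled-down study conditions for unit tests: 4 chromosomes, 3 wave
    archetypes, clearly separated from the noise."""
    return SimulationConfig(
        n_chromosomes=4,
        markers_per_chromosome=120,
        n_archetypes=3,
        lrr_noise_sd=0.1,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return simulate_cohort(small_cfg, 20)


@pytest.fixture(scope="session")
def small_model(small_cohort):
    return build_reference(
        small_cohort.samples, small_cohort.markers, k_range=(2, 8), seed=5
    )


@pytest.fixture
def tiny_markers():
    """10 markers on two chromosomes with round positions."""
    return MarkerMap(
        marker_id=[f"m{i}" for i in range(10)],
        chrom=["1"] * 6 + ["2"] * 4,
        position=[100, 200_000, 900_000, 1_000_000, 1_000_001, 2_500_000,
                  50_000, 400_000, 600_000, 1_200_000],
    )


def random_sample(markers, rng, missing_frac=0.1, sample_id="S"):
    n = len(markers)
    lrr = rng.normal(0, 0.2, n)
    baf = rng.uniform(0, 1, n)
    lrr[rng.random(n) < missing_frac] = np.nan
    baf[rng.random(n) < missing_frac] = np.nan
    genotype = rng.choice(["AA", "AB", "BB", "NC"], n)
    return SignalSample(sample_id, lrr, baf, genotype)
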