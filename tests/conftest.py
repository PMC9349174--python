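import pytest
from hypothesis import HealthCheck, settings

from oometh import Chromosome, GenomeLayout, SimulationConfig, generate_cohort, make_bin_grid

settings.register_profile(
    "det", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def tiny_layout():
    return GenomeLayout(
        (
            Chromosome("chr1", 100_000, "autosome"),
            Chromosome("chr2", 25_000, "autosome"),
            Chromosome("chrX", 60_000, "chrX"),
        )
    )


@pytest.fixture(scope="session")
def tiny_grid(tiny_layout):
    return make_bin_grid(tiny_layout, 10_000)


@pytest.fixture(scope="session")
def small_config():
    # small genome keeps simulation-heavy tests fast while leaving ~500 bins;
    # the genic fraction is raised so the closed-form calibration stays
    # feasible at this scale (fewer, shorter genes realize a smaller bin
    # fraction than the default genome)
    return SimulationConfig(
        seed=7,
        autosome_lengths=(2_000_000, 2_000_000),
        chrx_length=1_000_000,
        genic_fraction=0.32,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)
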