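import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from irradgbs import synthetic_gbs as sg  # noqa: E402


@pytest.fixture(scope="session")
def clean_sim():
    """Small noise-free dataset: both study designs, error rate 0."""
    config = sg.SimConfig(
        n_chromosomes=3,
        chrom_length=3_000_000,
        n_regions=5_000,
        region_length_mean=144,
        snp_rate=4e-4,
        xo_rate=1.0,
        mutation_density=30.0,
        depth_mean=30,
        depth_dispersion=20,
        genotype_error_rate=0.0,
        n_controls=4,
        n_mutants_per_group=3,
        mutant_groups=("pistil_60Gy", "seed_60Gy"),
        n_progeny=8,
        seed=7,
    )
    return sg.simulate_dataset(config)


@pytest.fixture(scope="session")
def clean_pools(clean_sim):
    man = clean_sim.manifest

    def pool(role):
        return list(man.loc[man["role"] == role, "sample"])

    return {role: pool(role) for role in
            ("parentA", "parentB", "f1", "control", "mutant", "progeny")}
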