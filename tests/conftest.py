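import pytest

from nanocage.synthetic_data import (
    SimulationConfig,
    preset_samples,
    simulate_library,
    simulate_reference,
)


@pytest.fixture(scope="session")
def chem_sim():
    """Small three-chemistry simulation with sequencing errors."""
    cfg = SimulationConfig(
        seed=5,
        genome_length=120_000,
        n_genes=30,
        reads_per_sample=1200,
        n_invasion_sites=20,
        samples=preset_samples(["R3", "L3", "D3"]),
    )
    ref = simulate_reference(cfg)
    records, truth = simulate_library(cfg, ref)
    return cfg, ref, records, truth


@pytest.fixture(scope="session")
def error_free_sim():
    """Error-free single-sample simulation for exact round-trip checks."""
    cfg = SimulationConfig(
        seed=11,
        genome_length=120_000,
        n_genes=30,
        reads_per_sample=2000,
        n_invasion_sites=20,
        error_rate=0.0,
        samples=preset_samples(["R3"]),
    )
    ref = simulate_reference(cfg)
    records, truth = simulate_library(cfg, ref)
    return cfg, ref, records, truth
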