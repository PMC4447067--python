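import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_tables():
    """Packaged regulon peak records plus the reconstructed annotation."""
    from sigchip import regulon_tables

    records, annotation = regulon_tables.load_fixture()
    return records, annotation


@pytest.fixture(scope="session")
def small_simulation():
    """One seeded simulation shared by read-only tests: genome, libraries, truth."""
    from sigchip.synthetic import SimulationParams, generate_genome, simulate_libraries
    from sigchip.tracks import coverage_from_fragments

    params = SimulationParams(n_sites=5, depth=50_000, seed=7)
    sequence, genes, truth = generate_genome(params)
    ip, inp = simulate_libraries(sequence, truth.sites, params)
    return {
        "params": params,
        "sequence": sequence,
        "genes": genes,
        "truth": truth,
        "ip": ip,
        "input": inp,
        "ip_cov": coverage_from_fragments(ip),
        "input_cov": coverage_from_fragments(inp),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
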