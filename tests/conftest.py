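import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from cotarget import (
    assign_peaks_to_genes,
    simulate_cooccupancy,
    simulate_genome,
)


@pytest.fixture(scope="session")
def small_genome():
    return simulate_genome(60, n_chroms=2, seed=5)


@pytest.fixture(scope="session")
def planted(small_genome):
    """A small planted co-occupancy study with both assignments done."""
    ps_a, ps_b, truth = simulate_cooccupancy(
        small_genome, n_targets_a=30, n_targets_b=20, n_shared=12,
        sigma_shared_bp=40.0, seed=7,
    )
    assign_a = assign_peaks_to_genes(ps_a, small_genome)
    assign_b = assign_peaks_to_genes(ps_b, small_genome)
    return small_genome, ps_a, ps_b, truth, assign_a, assign_b
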