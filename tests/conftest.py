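import numpy as np
import pytest

from circulome.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def default_sim():
    """One study-scale synthetic dataset shared across tests (sequence-free:
    interval/annotation statistics don't need the circle sequences)."""
    return simulate(SimConfig(seed=11, emit_sequences=False))


@pytest.fixture(scope="session")
def small_seq_sim():
    """A small dataset with real sequences, short circles, and planted
    redundant copies, cheap enough for alignment-based stages."""
    cfg = SimConfig(
        genome_length=400_000,
        n_chromosomes=2,
        n_unanchored=1,
        unanchored_length=10_000,
        circles_per_sample=40,
        length_mean=600.0,
        length_min=31,
        length_max=3_000,
        window_size=50_000,
        hotspot_windows=(),
        gene_density_beta=0.0,
        n_genes=60,
        n_tes=40,
        qtl_plan=None,
        duplicate_fraction=0.15,
        seed=7,
    )
    return simulate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
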