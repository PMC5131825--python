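import numpy as np
import pytest

from zfdiv.synthetic import SyntheticWorldConfig, generate_world


@pytest.fixture(scope="session")
def default_world():
    """One full-size synthetic world shared across tests (read-only)."""
    return generate_world(SyntheticWorldConfig(seed=11))


@pytest.fixture(scope="session")
def small_world():
    """A deliberately small world for fast structural checks."""
    cfg = SyntheticWorldConfig(
        seed=5,
        genome_length=300_000,
        n_chromosomes=2,
        n_proteins=6,
        n_clusters=2,
        peaks_per_protein=100,
        n_tss=60,
        n_dhs=40,
        ere_classes=[("LINE", 30, 400), ("SINE", 60, 150), ("LTR", 20, 350)],
    )
    return generate_world(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
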