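import numpy as np
import pytest

from saltlnc.simulate import (
    SimulationConfig,
    simulate_genome,
    simulate_transcript_set,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """A compact study: fast, but exercising every feature type."""
    return SimulationConfig(
        seed=7,
        n_chroms=2,
        chrom_length=120_000,
        n_coding_genes=25,
        n_lincRNAs=20,
        n_lncNATs=8,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return simulate_genome(small_cfg)


@pytest.fixture(scope="session")
def small_transcripts(small_cfg, small_study):
    return simulate_transcript_set(small_cfg, small_study)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def random_sequence(rng, n: int, with_ambiguity: bool = False) -> str:
    alphabet = "ACGTN" if with_ambiguity else "ACGT"
    p = [0.23, 0.23, 0.23, 0.23, 0.08] if with_ambiguity else None
    return "".join(rng.choice(list(alphabet), size=n, p=p))
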