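import numpy as np
import pytest

from m6ascreen import synth


@pytest.fixture(scope="session")
def default_config():
    return synth.SynthConfig(seed=7)


@pytest.fixture(scope="session")
def planted_tables(default_config):
    """One planted-family instance shared across homology tests."""
    families, roster = synth.simulate_families(default_config)
    table = synth.simulate_hit_table(families, default_config)
    return families, roster, table


@pytest.fixture()
def rng():
    return np.random.default_rng(20240723)


def random_transcript(rng, length=1000, n_frac=0.0):
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=length)
    if n_frac > 0:
        mask = rng.random(length) < n_frac
        seq[mask] = "N"
    return "".join(seq)
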