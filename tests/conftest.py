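import numpy as np
import pytest

import sedlineage as sl


@pytest.fixture(scope="session")
def strong_env_dataset():
    """One strong-preset environment-scenario study, shared across tests."""
    return sl.simulate_dataset(sl.strong_preset("environment", seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_lineages():
    return sl.LineageSet(
        ["l1", "l2", "l3"], ["ACGTACGT", "ACGTACGA", "ACCTACGA"], "toy_8"
    )


def random_lineage_set(rng, n=8, length=67, prefix="lin"):
    """Random, pairwise-distinct aligned sequences."""
    bases = np.array(list("ACGT"))
    seqs = set()
    while len(seqs) < n:
        seqs.add("".join(rng.choice(bases, size=length)))
    seqs = sorted(seqs)
    return sl.LineageSet([f"{prefix}_{i:02d}" for i in range(n)], seqs, f"rand_{length}")
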