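import numpy as np
import pytest

from symdiv.seq_io import AlignedPool


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_pool(rng, n=20, length=30, n_hap=6, pool_id="p", origin="soil",
                species="sp1"):
    """Random pool drawn from a small haplotype set (guarantees repeats)."""
    haps = ["".join(rng.choice(list("ACGT"), size=length)) for _ in range(n_hap)]
    seqs = [haps[i] for i in rng.integers(0, n_hap, size=n)]
    return AlignedPool(pool_id=pool_id, species=species, origin=origin,
                       sequences=seqs)


@pytest.fixture
def small_pool(rng):
    return random_pool(rng)


def make_pool(seqs, pool_id="p", origin="soil", species="sp1"):
    return AlignedPool(pool_id=pool_id, species=species, origin=origin,
                       sequences=list(seqs))
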