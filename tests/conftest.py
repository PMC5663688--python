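import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mfakit.coverage import WindowScheme
from mfakit.fragments import FragmentSet
from mfakit.genome import GenomeRecord

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_genome(rng):
    """10 kb circular genome, roughly balanced composition."""
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    return GenomeRecord(id="chr", sequence=seq, circular=True)


@pytest.fixture
def default_scheme():
    return WindowScheme(window_size=1000, step=500, circular=True)


def brute_force_window_coverage(fragments: FragmentSet, L: int,
                                scheme: WindowScheme) -> np.ndarray:
    """Independent per-base accumulation oracle for window coverage."""
    depth = np.zeros(L, dtype=np.int64)
    for frag in fragments:
        for block in frag.blocks:
            depth[block.start:block.end] += 1
    W, S = scheme.window_size, scheme.step
    if scheme.circular:
        n = -(-L // S)
        cov = np.empty(n, dtype=np.int64)
        for i in range(n):
            idx = (i * S + np.arange(W)) % L
            cov[i] = depth[idx].sum()
    else:
        n = (L - W) // S + 1
        cov = np.array([depth[i * S:i * S + W].sum() for i in range(n)])
    return cov


def random_fragment_set(rng, L: int, n: int, min_len: int = 20,
                        max_len: int = 400, chrom: str = "chr") -> FragmentSet:
    """Random single-block fragments plus circular wrap splits."""
    starts = rng.integers(0, L, size=n)
    lengths = rng.integers(min_len, max_len + 1, size=n)
    ends = starts + lengths
    wrap = ends > L
    b1s = np.where(wrap, 0, starts)
    b1e = np.where(wrap, ends - L, ends)
    b2s = np.where(wrap, starts, -1)
    b2e = np.where(wrap, L, -1)
    strands = np.where(rng.random(n) < 0.5, 1, -1).astype(np.int8)
    b2strand = np.where(wrap, strands, 0).astype(np.int8)
    return FragmentSet(chrom, b1s, b1e, strands, b2s, b2e, b2strand)
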