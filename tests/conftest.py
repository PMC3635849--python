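import numpy as np
import pytest

from ventpop import synthetic_data as sd
from ventpop.seqio import LocusAlignment


def random_alignment(rng, n, L, alphabet="ACGT"):
    """Unstructured random alignment (for oracle-equivalence checks)."""
    base = rng.choice(list(alphabet), size=L)
    seqs = []
    for _ in range(n):
        s = base.copy()
        k = rng.integers(0, max(L // 4, 1) + 1)
        pos = rng.choice(L, size=k, replace=False)
        s[pos] = rng.choice(list(alphabet), size=k)
        seqs.append("".join(s))
    return LocusAlignment("toy", tuple(f"s{i}" for i in range(n)), tuple(seqs))


def two_pop_config(seed, **overrides):
    """Small two-region design for fast structured simulations."""
    defaults = dict(
        loci=(("locA", 300), ("locB", 201)),
        regions=[
            sd.Region("OT", [sd.Site("a", 27.8, 126.9, 4)]),
            sd.Region("SMT", [sd.Site("b", 12.9, 143.6, 6)]),
        ],
        seed=seed,
    )
    defaults.update(overrides)
    return sd.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size default simulation shared by the slower tests."""
    cfg = sd.default_config(seed=2024)
    alignments, truth = sd.simulate_sequences(cfg)
    peaks = sd.simulate_spectra(cfg, truth)
    return cfg, alignments, truth, peaks


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
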