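import numpy as np
import pytest

from mitodiv import Alignment, SimulationConfig, simulate_two_epoch


@pytest.fixture
def small_alignment():
    return Alignment.from_strings(
        ["a", "b", "c", "d"],
        ["ACGTACGTAC", "ACGTACGTAC", "ACCTACGTAC", "ACCTACGAAC"],
    )


@pytest.fixture(scope="session")
def two_epoch_data():
    """One simulated study (mitogenome regime, scaled-down length)."""
    cfg = SimulationConfig(theta=11.7, L=2000, seed=20260928)
    hist, mod, groups = simulate_two_epoch(cfg)
    pooled = Alignment(hist.ids + mod.ids, np.vstack([hist.data, mod.data]))
    return pooled, groups


def random_alignment(rng, n, L, n_missing=0):
    """Random ACGT alignment with optional scattered N sites."""
    bases = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
    data = rng.choice(bases, size=(n, L))
    for _ in range(n_missing):
        data[rng.integers(n), rng.integers(L)] = b"N"
    return Alignment(tuple(f"s{i}" for i in range(n)), data)
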