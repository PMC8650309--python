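"""Shared fixtures: tiny pedigrees and a random-pedigree generator."""
import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def trio_pedigree():
    """Sire, dam and one offspring."""
    return pd.DataFrame({"animal": [1, 2, 3], "sire": [0, 0, 1], "dam": [0, 0, 2]})


@pytest.fixture
def fullsib_mating_pedigree():
    """Two founders, two full sibs, and an offspring of the full-sib mating."""
    return pd.DataFrame({
        "animal": [1, 2, 3, 4, 5],
        "sire": [0, 0, 1, 1, 3],
        "dam": [0, 0, 2, 2, 4],
    })


def random_pedigree(n: int, seed: int, p_unknown: float = 0.15) -> pd.DataFrame:
    """Random overlapping-generation pedigree with some inbreeding.

    Each animal draws its parents from the preceding animals (when any),
    with a chance of unknown parents; late animals may mate close relatives,
    so inbreeding arises naturally.
    """
    rng = np.random.default_rng(seed)
    sire = np.zeros(n, dtype=np.int64)
    dam = np.zeros(n, dtype=np.int64)
    for i in range(n):
        if i < 4:
            continue
        lo = max(0, i - 60)
        if rng.random() > p_unknown:
            sire[i] = rng.integers(lo, i) + 1
        if rng.random() > p_unknown:
            d = rng.integers(lo, i) + 1
            dam[i] = 0 if d == sire[i] else d
    return pd.DataFrame({"animal": np.arange(1, n + 1), "sire": sire, "dam": dam})


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
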