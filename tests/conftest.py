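import numpy as np
import pytest

from pprlink import (
    CLK,
    EncodingConfig,
    corruption_model,
    encode_dataset,
    generate_population,
    parameter_set,
)

SECRET = "test-secret-42"


@pytest.fixture
def config():
    return EncodingConfig(secret=SECRET)


@pytest.fixture
def pset1():
    return parameter_set("set1")


@pytest.fixture
def small_population():
    """~150-record truth-linked population with light corruption."""
    model = corruption_model("wa", typo_rate=0.08, field_swap_rate=0.02)
    return generate_population(100, 0.5, model, seed=20240101)


@pytest.fixture
def small_clks(small_population, pset1, config):
    return encode_dataset(small_population.records, pset1, config)


def random_clks(rng: np.random.Generator, n: int, l: int, density=(0.1, 0.4)):
    """Random-bit CLKs with per-vector densities drawn from ``density``."""
    clks = []
    for i in range(n):
        p = rng.uniform(*density)
        bits = (rng.random(l) < p).astype(np.uint8)
        clks.append(CLK(record_id=f"X{i:05d}", bits=np.packbits(bits), l=l))
    return clks


def brute_force_pair_set(clks, threshold):
    """Independent O(n^2) oracle on unpacked boolean matrices (no package calls)."""
    n = len(clks)
    mat = np.stack([np.unpackbits(c.bits, count=c.l) for c in clks]).astype(np.int64)
    pops = mat.sum(axis=1)
    found = set()
    for i in range(n):
        inter = (mat[i + 1 :] & mat[i]).sum(axis=1)
        union = pops[i] + pops[i + 1 :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            sims = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
        for off in np.flatnonzero(sims >= threshold):
            j = i + 1 + int(off)
            a, b = clks[i].record_id, clks[j].record_id
            found.add((a, b) if a < b else (b, a))
    return found
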