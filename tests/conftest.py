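import numpy as np
import pandas as pd
import pytest

from spikedyn.io import SpikeTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    """Three neurons, a handful of spikes, 10 ms recording."""
    df = pd.DataFrame(
        {
            "neuron_id": ["a", "a", "a", "b", "b", "c"],
            "time_ms": [0.2, 0.7, 4.0, 1.1, 9.9, 5.5],
        }
    )
    return SpikeTable(df, condition="control", culture_id="cx", duration_ms=10.0)


def markov_chain(n: int, flip_p: float, seed: int) -> np.ndarray:
    """Symmetric two-state Markov chain via cumulative XOR of flip events."""
    rng = np.random.default_rng(seed)
    flips = (rng.random(n) < flip_p).astype(np.uint8)
    flips[0] = rng.random() < 0.5
    return np.cumsum(flips, dtype=np.int64).astype(np.uint8) & 1


def exhaustive_entropy(series) -> float:
    """Histogram-by-hand plug-in entropy oracle (bits)."""
    from collections import Counter
    import math

    c = Counter(list(series))
    n = sum(c.values())
    return -sum((k / n) * math.log2(k / n) for k in c.values())


def exhaustive_cmi(y, x, c) -> float:
    """Dictionary-counting I(Y; X | C) oracle (bits)."""
    from collections import Counter
    import math

    n = len(x)
    jyxc = Counter(zip(y, x, c))
    jyc = Counter(zip(y, c))
    jxc = Counter(zip(x, c))
    jc = Counter(c)
    total = 0.0
    for (yy, xx, cc), k in jyxc.items():
        total += (k / n) * math.log2(k * jc[cc] / (jyc[yy, cc] * jxc[xx, cc]))
    return total
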