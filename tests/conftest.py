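import numpy as np
import pandas as pd
import pytest

from epirepress import synthio


@pytest.fixture(scope="session")
def small_cfg() -> synthio.SynthConfig:
    """A scaled-down study: enough probes/genes for signal, fast to generate."""
    return synthio.SynthConfig(seed=7, n_probes=4000, n_genes=600,
                               n_repressed_genes=30)


@pytest.fixture(scope="session")
def meth_dataset(small_cfg):
    return synthio.make_methylation_dataset(small_cfg)


def brute_force_es(scores: np.ndarray, genes: list[str], members: set[str],
                   weight_p: float) -> float:
    """Independent running-sum oracle: explicit walk down the ranked list."""
    hits = [g in members for g in genes]
    n = len(genes)
    nh = sum(hits)
    nr = sum(abs(s) ** weight_p for s, h in zip(scores, hits) if h)
    total = 0.0
    walk = []
    for s, h in zip(scores, hits):
        if h:
            total += (abs(s) ** weight_p / nr) if nr > 0 else 1.0 / nh
        elif n > nh:
            total -= 1.0 / (n - nh)
        walk.append(total)
    best, worst = max(walk), min(walk)
    return best if best >= -worst - 1e-12 else worst
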