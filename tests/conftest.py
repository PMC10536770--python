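import numpy as np
import pytest

from genefam.synthetic import _core16, simulate_gene_family


@pytest.fixture(scope="session")
def core16_quiet():
    """core16 simulations at reduced event density with loss rate 0,
    shared across tests that compare against logged truth."""
    out = []
    for seed in range(1, 21):
        st, cfg = _core16()
        cfg.rates = {k: (0.0 if k == "loss" else v * 0.5) for k, v in cfg.rates.items()}
        gt, log, loci = simulate_gene_family(st, cfg, seed)
        if gt is not None:
            out.append((st, gt, log, loci))
    assert out
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20230915)
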