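import numpy as np
import pytest

from kodep import LineageSimConfig, TfnseqSimConfig, simulate_lineage, simulate_tfnseq_library

K0 = float(np.log(2))


@pytest.fixture(scope="session")
def k0() -> float:
    return K0


@pytest.fixture(scope="session")
def clean_lineage_o4():
    """Zero-noise lineage with fourfold overabundance (arrest at t = 2 h)."""
    return simulate_lineage(LineageSimConfig(o_true=4.0, t_max=5.0, seed=1))


@pytest.fixture(scope="session")
def balanced_library():
    """Balanced 300-gene knockout library with its truth table."""
    cfg = TfnseqSimConfig(seed=3)
    counts, truth = simulate_tfnseq_library(cfg)
    return cfg, counts, truth
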