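import numpy as np
import pytest

from avaseq import synthetic
from avaseq.parsing import SpikeEnsemble


@pytest.fixture
def hand_sequence():
    """The worked transition-counting example sequence."""
    return np.array([0, 1, 2, 0, 0, 2, 1, 1, 0])


@pytest.fixture
def small_ensemble():
    return SpikeEnsemble({
        1: np.array([0.0, 0.03, 0.15]),
        2: np.array([0.06]),
    })


@pytest.fixture(scope="session")
def planted_first_order():
    """One 50k-symbol session with 2-fold RUN enrichment (15 cells)."""
    cfg = synthetic.SleepSynthConfig(n_symbols=50_000, enrichment_factor=2.0, seed=7)
    seq, chain = synthetic.generate_burst_markov(cfg)
    return cfg, seq, chain


def second_order_config(seed: int, factor: float = 4.0) -> synthetic.SleepSynthConfig:
    """Small (6-cell) ensemble with planted second-order triples along RUN.

    The small alphabet keeps the modulated digram contexts above the PST
    frequency threshold so the depth-2 structure is learnable.
    """
    rs = (1, 2, 3, 4, 5)
    boosts = {}
    for a, b, c in zip(rs[:-2], rs[1:-1], rs[2:]):
        boosts[(a, b)] = {c: factor}
    return synthetic.SleepSynthConfig(
        n_cells=6, run_sequence=rs, n_symbols=50_000, enrichment_factor=2.0,
        second_order_boosts=boosts, seed=seed,
    )
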