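import numpy as np
import pytest

from helpers import random_blocks, table_from_blocks


@pytest.fixture
def rng():
    return np.random.default_rng(20_2009)


@pytest.fixture
def small_table():
    """Two participants, clean latencies, one error each: a well-behaved table."""
    blocks = {
        "p1": {
            "practice_A": [(500, 1), (700, 1), (650, 1)],
            "test_A": [(550, 1), (720, 1), (610, 0)],
            "practice_B": [(700, 1), (900, 1), (820, 1)],
            "test_B": [(760, 1), (880, 1), (940, 1)],
        },
        "p2": {
            "practice_A": [(620, 1), (580, 1), (710, 0)],
            "test_A": [(640, 1), (590, 1), (660, 1)],
            "practice_B": [(850, 1), (780, 1), (910, 1)],
            "test_B": [(800, 1), (830, 0), (870, 1)],
        },
    }
    return table_from_blocks(blocks)


@pytest.fixture
def random_table(rng):
    """Twenty random micro-participants (2-8 trials/block, mixed errors)."""
    blocks = {f"r{i:02d}": random_blocks(rng) for i in range(20)}
    return table_from_blocks(blocks)
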