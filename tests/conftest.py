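import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

GRID_MS = 1000.0 / 128.0  # Holter sampling grid


def random_grid_rr(rng: np.random.Generator, n: int | None = None,
                   zero_bias: bool = True) -> np.ndarray:
    """Random RR series (ms) on the 1/128 s grid, with frequent repeats."""
    if n is None:
        n = int(rng.integers(3, 90))
    steps = rng.integers(40, 200, size=n)  # 312.5 .. 1562.5 ms
    if zero_bias:  # force repeated values so neutral runs occur
        repeat = rng.random(n) < 0.35
        for i in range(1, n):
            if repeat[i]:
                steps[i] = steps[i - 1]
    return steps * GRID_MS


@pytest.fixture
def rng():
    return np.random.default_rng(20240296)


@pytest.fixture
def worked_example():
    """The short tachogram used throughout the docs: one DR2, one AR2, one NR1."""
    return [800.0, 850.0, 900.0, 850.0, 800.0, 800.0]
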