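import numpy as np
import pytest

from clonedemix import AggregateSignal, CloneTree, build_signal

# Worked-example fixture used across the suite: six entries (dummy first),
# exact frequencies with four populated subclones and a unique optimum.
WEX_Y = (1.00, 0.72, 0.40, 0.28, 0.25, 0.15)
WEX_LABELS = ("dummy", "a2", "a3", "a4", "a5", "a6")
WEX_PARENTS = (-1, 0, 1, 0, 2, 2)
WEX_X = (0.0, 0.32, 0.0, 0.28, 0.25, 0.15)


def make_signal(y, eps=None, labels=None) -> AggregateSignal:
    y = np.asarray(y, dtype=float)
    eps = np.zeros_like(y) if eps is None else np.asarray(eps, dtype=float)
    if labels is None:
        labels = ("dummy",) + tuple(f"a{i+1}" for i in range(1, len(y)))
    return AggregateSignal(tuple(labels), y, eps)


@pytest.fixture
def wex_signal() -> AggregateSignal:
    return make_signal(WEX_Y, labels=WEX_LABELS)


@pytest.fixture
def wex_signal_bound() -> AggregateSignal:
    eps = (0.0,) + (0.02,) * 5
    return make_signal(WEX_Y, eps=eps, labels=WEX_LABELS)


@pytest.fixture
def wex_tree() -> CloneTree:
    return CloneTree(WEX_PARENTS)


def random_parent_array(n: int, rng: np.random.Generator) -> CloneTree:
    return CloneTree([-1] + [int(rng.integers(0, j)) for j in range(1, n)])


def random_exact_signal(rng: np.random.Generator, n: int) -> AggregateSignal:
    """A signal with distinct random frequencies (no planted structure)."""
    while True:
        vals = np.sort(rng.uniform(0.02, 0.98, size=n - 1))[::-1]
        if n == 1 or np.min(np.abs(np.diff(np.concatenate(([1.0], vals))))) > 1e-3:
            break
    return make_signal(np.concatenate(([1.0], vals)))
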