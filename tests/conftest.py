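import numpy as np
import pytest

from plsm.benchmarks import BENCHMARKS, load_problem, run_benchmark


@pytest.fixture(scope="session")
def problems():
    """All six packaged benchmark problems, parsed once."""
    return {ident: load_problem(ident) for ident in BENCHMARKS}


class _RunCache:
    """Solve each benchmark at its published settings at most once."""

    def __init__(self):
        self._runs = {}

    def __call__(self, identifier, **kw):
        key = (identifier, tuple(sorted(kw.items())))
        if key not in self._runs:
            self._runs[key] = run_benchmark(identifier, **kw)
        return self._runs[key]


@pytest.fixture(scope="session")
def bench():
    return _RunCache()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
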