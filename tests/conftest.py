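"""Shared fixtures.

The heavyweight fixture is ``pipeline_runs``: three full
simulate -> integrate -> match -> evaluate runs at the scaled-down study
size (8000 cells, 256 features, 64+64 epochs, k=64, p=95), shared by every
test that scores the end-to-end pipeline.
"""

import pytest

from scmatch.pipeline import run_simulated_benchmark
from scmatch.simulate import generate_technologies, make_default_tree


@pytest.fixture(scope="session")
def tree():
    return make_default_tree()


@pytest.fixture(scope="session")
def small_pair(tree):
    """Two small technologies from the shared tree (unit-test scale)."""
    return generate_technologies(tree, 2, 1200, 48, [11, 22])


@pytest.fixture(scope="session")
def pipeline_runs():
    return [run_simulated_benchmark(seed) for seed in (1, 2, 3)]
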