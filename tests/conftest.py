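import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))

from srma.variant_graph import VariantGraph  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def linear_graph():
    """Reference-only graph over a 12-base reference, depth 3."""
    ref = "ACGTACGTACGT"
    g = VariantGraph(ref)
    for _ in range(3):
        g.add_alignment(ref, 1, f"{len(ref)}M")
    return g
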