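import numpy as np
import pytest

from spotalign.graph import build_graph
from spotalign.io import STSlice


@pytest.fixture
def toy_slice():
    """4 spots x 5 genes with integer counts, labels and grid coordinates."""
    counts = np.array([
        [5, 0, 3, 1, 2],
        [0, 4, 2, 2, 1],
        [1, 1, 6, 0, 3],
        [2, 3, 0, 5, 0],
    ], dtype=float)
    return STSlice(
        slice_id="toy",
        expr=np.log1p(counts),
        coords=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]),
        genes=[f"g{i}" for i in range(5)],
        labels=np.array(["a", "a", "b", "b"]),
        raw_counts=counts,
        raw_genes=[f"g{i}" for i in range(5)],
    )


@pytest.fixture
def line_toy():
    """5 spots on a line (adjacent-only neighbors) with random features.

    Neighborhoods are all distinct, so the latent embeddings are well
    separated — suitable for finite-difference gradient checks.
    """
    coords = np.column_stack([np.arange(5.0), np.zeros(5)])
    graph = build_graph(coords, radius=1.5)
    H0 = np.random.RandomState(0).randn(5, 4)
    return H0, graph
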