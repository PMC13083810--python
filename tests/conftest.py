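import numpy as np
import pandas as pd
import pytest

from nepscore import CellTable, build_delaunay
from nepscore.fixtures import infiltrated_blob_tissue, thirty_cell_table, two_blob_tissue


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def thirty_cells():
    return thirty_cell_table(seed=7)


@pytest.fixture(scope="session")
def blobs():
    """Two spatially segregated blobs of types A and B."""
    return two_blob_tissue(n_per_blob=200, seed=5)


@pytest.fixture(scope="session")
def infiltrated():
    """Blob of B with a few infiltrating A cells: asymmetric fixture."""
    return infiltrated_blob_tissue(seed=9)


@pytest.fixture(scope="session")
def random_label_graph():
    """A fixed 400-cell Delaunay graph for null-calibration checks."""
    g = np.random.default_rng(31)
    pts = g.uniform(0, 1, size=(400, 2))
    return build_delaunay(pts)


def make_cells(pts, types, image_id="img", label_set=None) -> CellTable:
    pts = np.asarray(pts, dtype=float)
    return CellTable(
        pd.DataFrame(
            {
                "cell_id": np.arange(len(pts)),
                "x": pts[:, 0],
                "y": pts[:, 1],
                "cell_type": list(types),
                "image_id": image_id,
            }
        ),
        label_set=label_set,
    )
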