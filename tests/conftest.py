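import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from spiceist.io import UNASSIGNED, TranscriptTable

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def toy_table():
    """20 cells on a 40x40 µm slide with known per-cell totals.

    Cells c00..c19 at centers on a grid; cell c{i} has i+1 transcripts of
    alternating genes, plus 5 unassigned transcripts.
    """
    rows = []
    rng = np.random.default_rng(7)
    for i in range(20):
        cx, cy = 5.0 + (i % 5) * 8.0, 5.0 + (i // 5) * 10.0
        for t in range(i + 1):
            rows.append(
                {
                    "x": min(cx + rng.uniform(-2, 2), 39.9),
                    "y": min(cy + rng.uniform(-2, 2), 39.9),
                    "gene": ["gA", "gB", "gC"][t % 3],
                    "cell_id": f"c{i:02d}",
                }
            )
    for _ in range(5):
        rows.append(
            {"x": rng.uniform(0, 40), "y": rng.uniform(0, 40), "gene": "gA", "cell_id": UNASSIGNED}
        )
    return TranscriptTable(
        data=pd.DataFrame(rows), panel=["gA", "gB", "gC"], bounds=(0.0, 0.0, 40.0, 40.0)
    )


@pytest.fixture
def two_blob_embedding(rng):
    """100 points in two tight, far-separated blobs; labels attached."""
    a = rng.normal(scale=0.5, size=(50, 4))
    b = rng.normal(scale=0.5, size=(50, 4)) + 100.0
    X = np.vstack([a, b])
    labels = np.array([0] * 50 + [1] * 50)
    return X, labels
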