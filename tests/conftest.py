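import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from plaquesholl import Field


def make_cells(xs, ys, radius=5.0, is_microglia=1, intensity=None):
    """Small helper to build a schema-conformant cell table."""
    n = len(xs)
    return pd.DataFrame(
        {
            "id": [f"c{i}" for i in range(n)],
            "x_um": xs,
            "y_um": ys,
            "radius_um": np.full(n, radius),
            "is_microglia": np.full(n, is_microglia),
            "is_proliferating": np.zeros(n, dtype=int),
            "intensity": intensity if intensity is not None else np.full(n, np.nan),
        }
    )


def make_plaques(xs, ys, radii):
    return pd.DataFrame(
        {
            "id": [f"p{i}" for i in range(len(xs))],
            "x_um": xs,
            "y_um": ys,
            "radius_um": radii,
        }
    )


@pytest.fixture
def square_field():
    return Field(1000.0, 1000.0, reference_density_per_mm2=300.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
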