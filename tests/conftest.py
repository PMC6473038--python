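from pathlib import Path

import numpy as np
import pytest

from focimeta import Focus, FociDataset, VolumeGrid

DATA = Path(__file__).parent / "data"


@pytest.fixture
def data_dir() -> Path:
    return DATA


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240531)


@pytest.fixture
def small_grid() -> VolumeGrid:
    """An 11x11x11 grid at 2 mm spanning [-10, 10] mm on each axis."""
    return VolumeGrid.box((-10.0, -10.0, -10.0), (10.0, 10.0, 10.0), 2.0)


@pytest.fixture
def tiny_dataset() -> FociDataset:
    return FociDataset(
        (
            Focus("s1", "c1", "intention", (0.0, 0.0, 0.0)),
            Focus("s1", "c1", "intention", (2.0, 0.0, 0.0)),
            Focus("s2", "c1", "self_agency", (0.0, 2.0, 0.0)),
        )
    )


def two_blob_points(seed: int = 7, n: int = 20, sd: float = 3.0, sep: float = 40.0):
    """Two isotropic Gaussian blobs ``sep`` mm apart along x, n points each."""
    g = np.random.default_rng(seed)
    a = g.standard_normal((n, 3)) * sd
    b = g.standard_normal((n, 3)) * sd + np.array([sep, 0.0, 0.0])
    return np.vstack([a, b])
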