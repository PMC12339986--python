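import numpy as np
import pytest

from sppa.geometry import ObservationWindow, PointPattern
from sppa.models import simulate_csr


@pytest.fixture
def transect_window():
    """The canonical slender transect: 10 x 2 m rectangle."""
    return ObservationWindow.rectangle(0, 0, 10, 2)


@pytest.fixture
def octagon_window():
    rng = np.random.default_rng(7)
    angles = np.sort(rng.uniform(0, 2 * np.pi, 8))
    radii = rng.uniform(2, 4, 8)
    verts = np.column_stack([5 + radii * np.cos(angles),
                             5 + radii * np.sin(angles)])
    return ObservationWindow(verts)


@pytest.fixture
def csr60(transect_window):
    return simulate_csr(transect_window, n=60, seed=314)


@pytest.fixture
def toy6(transect_window):
    """Six hand-placed points, several near edges/corners."""
    x = [0.3, 0.8, 1.2, 4.0, 4.3, 9.6]
    y = [0.2, 0.5, 1.8, 1.0, 1.2, 0.3]
    return PointPattern(x, y, transect_window)


@pytest.fixture
def marked_pattern(transect_window):
    rng = np.random.default_rng(5)
    n = 40
    x = rng.uniform(0, 10, 2 * n)
    y = rng.uniform(0, 2, 2 * n)
    marks = ["Pennatuloidea"] * n + ["Cerianthidae"] * n
    return PointPattern(x, y, transect_window, marks=marks)
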