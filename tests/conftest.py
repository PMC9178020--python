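import numpy as np
import pytest

from scpsd import OmicsMatrix, SimConfig, simulate


@pytest.fixture
def toy_matrix() -> OmicsMatrix:
    """5 features x 8 cells of reproducible positive values."""
    rng = np.random.default_rng(42)
    return OmicsMatrix(
        rng.gamma(2.0, 2.0, size=(5, 8)),
        [f"g{i}" for i in range(5)],
        [f"c{j}" for j in range(8)],
    )


@pytest.fixture
def zero_row_matrix() -> OmicsMatrix:
    values = np.array([[1.0, 2.0], [0.0, 0.0], [3.0, 4.0]])
    return OmicsMatrix(values, ["g0", "g1", "g2"], ["c0", "c1"])


@pytest.fixture(scope="session")
def clustered() -> OmicsMatrix:
    """Default-condition clustered synthetic counts (500 x 200, 4 clusters)."""
    return simulate(SimConfig(seed=7))


@pytest.fixture(scope="session")
def small_clustered() -> OmicsMatrix:
    """A quick 120 x 80 clustered matrix for cheaper end-to-end tests."""
    return simulate(SimConfig(n_features=120, n_cells=80, n_clusters=3, seed=3))
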