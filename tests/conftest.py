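import numpy as np
import pytest

from dhinducer.genodata import GenotypeMatrix, Marker
from dhinducer.simulate import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """Desk-scale synthetic study shared across tests (seeded, read-only)."""
    cfg = SimConfig(n_markers=800, n_dh_per_cross=8)
    return simulate_study(cfg, seed=42)


@pytest.fixture()
def toy_matrix():
    """3 lines x 4 markers, fully coded, no missing."""
    markers = [Marker(f"m{j}", "chr1", 100 * (j + 1)) for j in range(4)]
    calls = np.array(
        [[1, 1, -1, 1], [1, -1, -1, 1], [-1, 1, 1, 1]], dtype=np.int8
    )
    return GenotypeMatrix(["L1", "L2", "L3"], markers, calls)
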