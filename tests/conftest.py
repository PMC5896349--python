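import numpy as np
import pytest

from rmaflow.io_model import ArrayIntensities, ArraySet, ChipLayout, Probe


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def tiny_layout():
    """2 probesets x 2 PM probes on a 2x2 grid."""
    return ChipLayout(
        name="tiny",
        n_rows=2,
        n_cols=2,
        probes=[
            Probe("psA", x=0, y=0, is_pm=True),
            Probe("psA", x=1, y=0, is_pm=True),
            Probe("psB", x=0, y=1, is_pm=True),
            Probe("psB", x=1, y=1, is_pm=True),
        ],
    )


@pytest.fixture
def pm_mm_layout():
    """One probeset with 3 PM and 3 MM probes on a 2x3 grid."""
    probes = []
    for k in range(3):
        probes.append(Probe("ps1", x=k, y=0, is_pm=True))
        probes.append(Probe("ps1", x=k, y=1, is_pm=False))
    return ChipLayout(name="pmmm", n_rows=2, n_cols=3, probes=probes)


def make_arrayset(layout: ChipLayout, grids: list[np.ndarray]) -> ArraySet:
    arrays = [
        ArrayIntensities(array_id=f"a{i}", values=g) for i, g in enumerate(grids)
    ]
    return ArraySet(layout=layout, arrays=arrays)


@pytest.fixture
def make_set():
    return make_arrayset
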