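import numpy as np
import pytest

from ftirswa import Spectrum, SpectrumGroup


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture
def small_grid():
    """Short ascending grid, 2 cm^-1 spacing."""
    return np.arange(600.0, 700.0 + 1, 2.0)


def make_group(condition, absorbance_rows, grid):
    return SpectrumGroup(
        condition,
        [
            Spectrum(grid, row, condition=condition, replicate=i + 1)
            for i, row in enumerate(absorbance_rows)
        ],
    )


@pytest.fixture
def noise_groups(rng, small_grid):
    """Two 3-replicate groups of pure iid noise on one grid (null case)."""
    m = small_grid.size
    return [
        make_group("a", rng.standard_normal((3, m)), small_grid),
        make_group("b", rng.standard_normal((3, m)), small_grid),
    ]
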