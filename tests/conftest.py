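import numpy as np
import pytest

from phasecell import Grid, ModelParams, PatternSpec, ScalarField2D
from phasecell.phasefield import make_disk


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def free_grid():
    return Grid.centered(80.0, 80.0, 1.0)


@pytest.fixture
def disk(params, free_grid):
    """Analytic logistic disk of the default target radius at the origin."""
    return make_disk(free_grid, (0.0, 0.0), params.R0, params.lam)


@pytest.fixture
def two_state():
    return PatternSpec(kind="two_state")


@pytest.fixture
def zero_field(free_grid):
    return ScalarField2D(np.zeros(free_grid.shape), free_grid)
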