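import numpy as np
import pytest

from linefpt.movestats import MovementParams
from linefpt.synthetic import Domain, Landscape, PreyConfig


@pytest.fixture
def square10() -> Domain:
    return Domain.square(10.0)


@pytest.fixture
def one_line_landscape() -> Landscape:
    """A single horizontal centreline at y = 2 on a 10 x 4 km domain."""
    return Landscape(np.array([[0.0, 2.0, 10.0, 2.0]]), Domain(0, 0, 10, 4))


@pytest.fixture
def cross_landscape() -> Landscape:
    """Axis-aligned lines (two horizontal, one vertical) on 4 x 4 km."""
    segs = np.array(
        [[0.0, 1.0, 4.0, 1.0], [0.0, 2.9, 4.0, 2.9], [1.9, 0.0, 1.9, 4.0]]
    )
    return Landscape(segs, Domain.square(4.0))


@pytest.fixture
def empty_landscape() -> Landscape:
    return Landscape(np.empty((0, 4)), Domain.square(10.0))


@pytest.fixture
def big_empty_landscape() -> Landscape:
    """Line-free 100 x 100 km domain: edge reflections are negligible, so
    fix-to-fix displacements carry the unperturbed step statistics."""
    return Landscape(np.empty((0, 4)), Domain.square(100.0))


@pytest.fixture
def iso_params() -> MovementParams:
    """Isotropic walk: equal step-length means, no concentration anywhere."""
    return MovementParams(
        alpha_on=0.0922, alpha_near=0.0922, alpha_off=0.0922, tau_minutes=5.0
    )


@pytest.fixture
def corner_prey() -> PreyConfig:
    return PreyConfig(
        np.array([[0.7, 0.6], [3.3, 0.7], [0.8, 3.4], [3.2, 3.3]]),
        0.45,
        Domain.square(4.0),
    )
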