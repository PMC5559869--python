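import numpy as np
import pytest

from vertrot import ShapeParams


@pytest.fixture
def pedicled_params() -> ShapeParams:
    """Pedicled endplate shape with a unique maximum-symmetry axis."""
    return ShapeParams()


@pytest.fixture
def ellipse_params() -> ShapeParams:
    """Pure ellipse: two perpendicular symmetry axes (the ambiguous case)."""
    return ShapeParams(
        pedicle_present=False, asymmetry_strength=0.0, body_exponent=2.0
    )


@pytest.fixture
def disc_params() -> ShapeParams:
    """Circular disc: symmetric about every diameter."""
    return ShapeParams(
        body_width=30.0, body_depth=30.0, pedicle_present=False,
        asymmetry_strength=0.0, body_exponent=2.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
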