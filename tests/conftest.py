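import numpy as np
import pytest

from luxcircuit import LuxReactionParams, PromoterParams


@pytest.fixture
def unit_lux() -> LuxReactionParams:
    """All rate/affinity constants set to 1 (the documented default units)."""
    return LuxReactionParams()


@pytest.fixture
def leaky_promoter() -> PromoterParams:
    return PromoterParams(vmax=1.0, K=1.0, n=1.0, basal=0.02)


@pytest.fixture
def six_decade_grid() -> np.ndarray:
    """The package's standard log-spaced dose window, 1e-3 .. 1e3."""
    return np.logspace(-3, 3, 200)
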