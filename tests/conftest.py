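import numpy as np
import pytest

from silersurv import (
    CONSTANT,
    AgeFrequencyData,
    SilerParams,
    constant_scenario,
    simulate_colony,
)


@pytest.fixture
def siler_params() -> SilerParams:
    """A full five-parameter set with all three hazard components active."""
    return SilerParams(a1=0.5, b1=1.0, a2=0.1, a3=0.01, b3=0.3, a=1.0, sigma=1.0)


@pytest.fixture
def constant_data() -> AgeFrequencyData:
    """One synthetic constant-risk colony (S=0.86, 1500 tooth-aged bats)."""
    _, data = simulate_colony(constant_scenario(0.86, 1500, seed=42))
    return data


def noise_free_constant_data(a2: float = 0.3, max_age: int = 12) -> AgeFrequencyData:
    """Exact geometric frequencies with amplitude 1 (no sampling noise)."""
    ages = np.arange(max_age + 1)
    return AgeFrequencyData(
        colony="exact", ages=ages, frequencies=np.exp(-a2 * ages), n_total=1000
    )
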