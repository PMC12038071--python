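import numpy as np
import pytest

from greyfly import AnnualSeries, GeneratorSpec, generate_grey_series


@pytest.fixture
def toy_series() -> AnnualSeries:
    """Short positive series with a mild upward trend."""
    return AnnualSeries(np.arange(2001, 2009), [7.0, 8.1, 9.5, 10.2, 12.0, 13.1, 15.4, 16.9])


@pytest.fixture
def ngbm_series() -> AnnualSeries:
    """Noiseless NGBM trajectory (gamma = -0.4), n = 12."""
    return generate_grey_series(
        GeneratorSpec(kind="NGBM", beta1=-0.05, beta2=2.0, gamma_power=-0.4,
                      initial_value=5.0, n=12)
    )


def random_positive_series(rng: np.random.Generator, n: int) -> np.ndarray:
    """Smooth strictly positive sequence suitable for grey fitting."""
    growth = rng.uniform(0.02, 0.15)
    base = rng.uniform(1.0, 50.0)
    noise = rng.normal(0.0, 0.02, n)
    return base * np.exp(growth * np.arange(n) + noise)
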