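import numpy as np
import pytest

from gagprofiler import Composition, LossVector, fit_intensity_model
from gagprofiler.simulate import FixtureSpec, generate_spectrum


@pytest.fixture(scope="session")
def intensity_model():
    """One fitted isotope-intensity model shared across the suite."""
    return fit_intensity_model(200.0, 4000.0, n_samples=70, degree=4, seed=0)


@pytest.fixture
def dp4_pair_spec():
    """Noiseless fixture with two distinct dp4 components and SO3 loss."""
    return FixtureSpec(
        components=[
            (Composition(1, 1, 2, 0, 5, 0, 0), 1e6),
            (Composition(0, 2, 2, 1, 3, 0, 0), 6e5),
        ],
        charges=(2, 3),
        losses=[LossVector(1, 0, 0, 0)],
        seed=11,
    )


@pytest.fixture
def dp4_pair_spectrum(dp4_pair_spec):
    return generate_spectrum(dp4_pair_spec)


def brute_force_distribution(formula, n_peaks):
    """Direct polynomial-convolution oracle for aggregated isotopologues."""
    from gagprofiler.isotopes import _abundance_polynomial

    poly = np.ones(1)
    for element, count in zip("CHNOS", formula):
        q = _abundance_polynomial(element)
        for _ in range(count):
            poly = np.convolve(poly, q)
    out = np.zeros(n_peaks)
    k = min(n_peaks, len(poly))
    out[:k] = poly[:k]
    return out
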