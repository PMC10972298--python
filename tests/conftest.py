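import numpy as np
import pytest

from urinmr.io import Spectrum
from urinmr.simulate import (
    CohortConfig,
    MetaboliteEntry,
    MetaboliteLibrary,
    MetabolitePeak,
    default_library,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def library():
    return default_library(20, seed=1)


@pytest.fixture(scope="session")
def cohort(library):
    """One default-condition synthetic cohort shared across read-only tests."""
    return simulate_cohort(CohortConfig(seed=42, points=2048), library)


@pytest.fixture()
def tiny_library():
    return MetaboliteLibrary(
        entries=[
            MetaboliteEntry("metab_a", [MetabolitePeak(2.0, 1.0, 0.02)]),
            MetaboliteEntry("metab_b", [MetabolitePeak(6.0, 0.5, 0.02)]),
        ]
    )


def make_spectrum(centers, heights=None, hwhm=0.02, window=(0.0, 9.0), points=3000):
    """Lorentzian test spectrum on a descending grid (helper, not a fixture)."""
    heights = heights if heights is not None else [1.0] * len(centers)
    ppm = np.linspace(window[1], window[0], points)
    y = np.zeros(points)
    for c, h in zip(centers, heights):
        y += h / (1.0 + ((ppm - c) / hwhm) ** 2)
    return Spectrum(ppm=ppm, intensity=y)
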