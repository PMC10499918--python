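import numpy as np
import pytest

from pykrm import MaterialSet, spheroid_fish
from pykrm.shapes import ShapeProfile


@pytest.fixture(scope="session")
def mats():
    """Survey acoustic parameters (water / fish body / swimbladder gas)."""
    return MaterialSet()


@pytest.fixture(scope="session")
def gas_sphere_5mm():
    """Gas sphere of 5 mm radius digitized finely, bladder-only in water."""
    return spheroid_fish((5.0, 5.0, 5.0), du_mm=0.1)


@pytest.fixture(scope="session")
def benchmark_spheroid():
    """The 15 x 2 mm gas prolate spheroid used for full-wave benchmarking."""
    return spheroid_fish((15.0, 2.0, 2.0), du_mm=0.25)


@pytest.fixture(scope="session")
def symmetric_fish():
    """Fore-aft symmetric spheroidal fish (body + centred bladder)."""
    return spheroid_fish(
        (10.0, 2.0, 3.0), body_semi_axes_mm=(40.0, 8.0, 6.0), du_mm=0.5
    )


def circle_profile(radius_mm: float, du_mm: float) -> ShapeProfile:
    """Semicircular sagittal outline (upper +sqrt, lower -sqrt), zero width."""
    n = int(round(2 * radius_mm / du_mm)) + 1
    u = np.linspace(-radius_mm, radius_mm, n)
    z = np.sqrt(np.clip(radius_mm**2 - u**2, 0.0, None))
    return ShapeProfile(u, z, -z, np.zeros_like(u))
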