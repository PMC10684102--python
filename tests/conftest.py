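import numpy as np
import pytest

from ltcov.pipeline import simulate_dataset
from ltcov.synthetic import SimulationConfig, make_icosphere


@pytest.fixture(scope="session")
def small_mesh():
    """Subdivision-3 icosphere (642 vertices) at cortical scale."""
    return make_icosphere(3, radius=70.0)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=11, n_parcels=60, mesh_subdivisions=3)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """Full synthetic bundle at desk scale (642 vertices, 60 parcels)."""
    return simulate_dataset(small_config)


def fibonacci_sphere(n: int, radius: float = 70.0) -> np.ndarray:
    """Quasi-uniform points on a sphere (stand-in for parcel centroids)."""
    idx = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * idx / n)
    theta = np.pi * (1 + 5**0.5) * idx
    return radius * np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def sphere_distances(coords: np.ndarray) -> np.ndarray:
    r = np.linalg.norm(coords[0])
    cos = np.clip(coords @ coords.T / r**2, -1, 1)
    return r * np.arccos(cos)


@pytest.fixture(scope="session")
def centroid_cloud():
    """120 quasi-uniform sphere centroids and their great-circle distances."""
    coords = fibonacci_sphere(120)
    return coords, sphere_distances(coords)
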