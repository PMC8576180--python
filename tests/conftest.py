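"""Shared fixtures: synthetic scenarios are expensive, build them once."""

import numpy as np
import pytest

from lungifea.surface_mesh import SurfaceMesh
from lungifea.synthetic_lung import SyntheticScenario, generate_cap_mesh


@pytest.fixture(scope="session")
def cap40():
    return generate_cap_mesh(40, seed=3)


@pytest.fixture(scope="session")
def cap120():
    return generate_cap_mesh(120, seed=7)


@pytest.fixture(scope="session")
def cap457():
    return generate_cap_mesh(457, seed=5)


@pytest.fixture(scope="session")
def homo_scenario():
    """Homogeneous Mooney-Rivlin truth on the 457-element cap, 7000 probes."""
    sc = SyntheticScenario(case="homo/iso/hyper", n_elements=457,
                           n_probes=7000, seed=42)
    return sc, sc.build()


@pytest.fixture(scope="session")
def homo_scenario_coarse():
    """Homogeneous Mooney-Rivlin truth on a 120-element cap, 300 probes."""
    sc = SyntheticScenario(case="homo/iso/hyper", n_elements=120,
                           n_probes=300, seed=7)
    return sc, sc.build()


@pytest.fixture(scope="session")
def iso_data_large_strain():
    """Isotropic MR truth in the finite-strain regime (peak 6 kPa, ~20-25%
    strain) — the regime where the HGO fiber term is identifiable."""
    sc = SyntheticScenario(case="homo/iso/hyper", n_elements=120,
                           n_probes=300, peak_pressure=6.0, seed=2)
    return sc, sc.build()


@pytest.fixture(scope="session")
def hetero_scenario():
    """Heterogeneous linear truth on a 40-element cap with boundary motion."""
    sc = SyntheticScenario(case="hetero/iso/linear", n_elements=40,
                           n_probes=150, boundary_amplitude=2.0, seed=3)
    return sc, sc.build()


def square_membrane(n: int, L: float = 100.0) -> SurfaceMesh:
    """Structured flat square mesh in the xy-plane (patch-test geometry)."""
    xs = np.linspace(0.0, L, n + 1)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), np.zeros((n + 1) ** 2)])

    def idx(i, j):
        return i * (n + 1) + j

    tris = []
    for i in range(n):
        for j in range(n):
            tris.append((idx(i, j), idx(i + 1, j), idx(i + 1, j + 1)))
            tris.append((idx(i, j), idx(i + 1, j + 1), idx(i, j + 1)))
    return SurfaceMesh(pts, np.array(tris), ap_axis=[0.0, 1.0, 0.0])
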