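import numpy as np
import pytest

from lh2exciton.config import load_bundle
from lh2exciton.exciton import AugmentedHamiltonian, CouplingMatrix, SiteBasis
from lh2exciton.geometry import PigmentGeometry, PigmentSpec, RingGeometry, build_ideal_ring


@pytest.fixture
def rng():
    return np.random.default_rng(20260131)


@pytest.fixture(scope="session")
def purp():
    return load_bundle("LH2purp")


@pytest.fixture(scope="session")
def acid():
    return load_bundle("LH2acid")


def nearest_neighbor_ring(n, coupling, site_energy=0.0):
    """Homogeneous circulant ring Hamiltonian with one pigment per unit."""
    v = np.zeros((n, n))
    for i in range(n):
        v[i, (i + 1) % n] = v[(i + 1) % n, i] = coupling
    return AugmentedHamiltonian(
        sites=SiteBasis(np.full(n, float(site_energy)), ("Qy",) * n),
        couplings=CouplingMatrix(v),
    )


def tangential_ring(n, radius=20.0, dipole_magnitude=6.3):
    """Ideal Cn ring with tangential in-plane dipoles (one pigment per unit)."""
    return build_ideal_ring(
        n, [PigmentSpec(dipole_magnitude=dipole_magnitude)], radius
    )


def single_pigment_ring(energy_label="Qy", magnitude=6.3, axis=(1.0, 0.0, 0.0)):
    return RingGeometry(
        [PigmentGeometry(f"1:{energy_label}", np.zeros(3), np.array(axis), magnitude)],
        1,
        1,
    )


def random_geometry(rng, n, magnitude=6.3):
    """Random pigment positions and dipole axes: used for sum-rule checks."""
    pigs = []
    for i in range(n):
        axis = rng.normal(size=3)
        pigs.append(
            PigmentGeometry(
                f"{i + 1}:Qy",
                rng.uniform(-20, 20, size=3),
                axis / np.linalg.norm(axis),
                magnitude,
            )
        )
    return RingGeometry(pigs, n, 1)


def random_hamiltonian(rng, n, energy_center=12500.0, energy_spread=300.0, vmax=200.0):
    e = energy_center + rng.uniform(-energy_spread, energy_spread, size=n)
    v = rng.uniform(-vmax, vmax, size=(n, n))
    v = 0.5 * (v + v.T)
    np.fill_diagonal(v, 0.0)
    return AugmentedHamiltonian(
        sites=SiteBasis(e, ("Qy",) * n), couplings=CouplingMatrix(v)
    )
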