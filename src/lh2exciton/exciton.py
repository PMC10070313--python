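"""CT-augmented Frenkel exciton Hamiltonians for pigment rings.

The electronic states of the aggregate are linear combinations of the locally
excited Qy states of the N_p pigments, optionally augmented with a manifold of
charge-transfer (CT) states between adjacent pigment pairs of the strongly
coupled ring.  The Hamiltonian carries site energies eps_i on the Qy diagonal,
excitonic couplings V_ij off-diagonal, CT energies on the CT diagonal and
Qy-CT couplings in the mixed block; CT-CT couplings vanish.  Dropping the CT
manifold recovers the standard Frenkel exciton Hamiltonian.

Per-state observables: transition dipoles and dipole strengths (CT states are
dark), exciton rotational strengths for circular dichroism, ring quantum
number k assigned by discrete Fourier analysis of the per-unit coefficient
pattern, and the inverse participation ratio as a measure of delocalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .geometry import RingGeometry

__all__ = [
    "SiteBasis",
    "CouplingMatrix",
    "CTManifold",
    "AugmentedHamiltonian",
    "ExcitonState",
    "assemble_hamiltonian",
    "diagonalize",
    "state_dipoles",
    "rotational_strengths",
    "k_labels",
    "band_summary",
    "circulant_eigenvalues",
    "write_hamiltonian",
    "read_hamiltonian",
    "write_states_table",
]


@dataclass(frozen=True)
class SiteBasis:
    """Per-site Qy excitation energies (cm^-1) and chain-class labels."""

    site_energies: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        e = np.atleast_1d(np.asarray(self.site_energies, dtype=float))
        if e.ndim != 1 or e.size < 1:
            raise ValueError("site_energies must be a non-empty 1-D array")
        if not np.all(np.isfinite(e)):
            raise ValueError("site energies must be finite")
        if len(self.classes) != e.size:
            raise ValueError("one class label per site required")
        object.__setattr__(self, "site_energies", e)
        object.__setattr__(self, "classes", tuple(self.classes))

    @property
    def n_sites(self) -> int:
        return self.site_energies.size


@dataclass(frozen=True)
class CouplingMatrix:
    """Symmetric excitonic coupling matrix V_ij (cm^-1) with zero diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("coupling matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("couplings must be finite")
        if np.max(np.abs(v - v.T)) > 1e-8:
            raise ValueError("coupling matrix is asymmetric beyond 1e-8 cm^-1")
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, 0.0)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class CTManifold:
    """Charge-transfer states between adjacent pigment pairs.

    ``adjacency[m]`` is the (i, j) site pair across which the m-th CT state
    separates charge; ``ct_couplings[i, m]`` may be nonzero only for
    i in adjacency[m] — CT states couple to the Qy excitations of their own
    pair only, as the charge-transfer interaction requires van der Waals
    contact.
    """

    ct_energies: np.ndarray
    ct_couplings: np.ndarray
    adjacency: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        e = np.atleast_1d(np.asarray(self.ct_energies, dtype=float))
        v = np.asarray(self.ct_couplings, dtype=float)
        if not np.all(np.isfinite(e)):
            raise ValueError("CT energies must be finite")
        if v.ndim != 2 or v.shape[1] != e.size:
            raise ValueError("ct_couplings must be (n_sites, n_ct)")
        if len(self.adjacency) != e.size:
            raise ValueError("one adjacency pair per CT state required")
        for m, pair in enumerate(self.adjacency):
            allowed = set(pair)
            bad = [i for i in np.nonzero(v[:, m])[0] if i not in allowed]
            if bad:
                raise ValueError(
                    f"CT state {m} (pair {pair}) couples to non-adjacent site(s) {bad}"
                )
        object.__setattr__(self, "ct_energies", e)
        object.__setattr__(self, "ct_couplings", v)
        object.__setattr__(self, "adjacency", tuple(tuple(p) for p in self.adjacency))

    @property
    def n_ct(self) -> int:
        return self.ct_energies.size


@dataclass(frozen=True)
class AugmentedHamiltonian:
    """Exciton Hamiltonian over N_p Qy sites plus an optional CT manifold."""

    sites: SiteBasis
    couplings: CouplingMatrix
    ct: CTManifold | None = None

    def __post_init__(self) -> None:
        if self.couplings.values.shape[0] != self.sites.n_sites:
            raise ValueError("coupling matrix size does not match number of sites")
        if self.ct is not None and self.ct.ct_couplings.shape[0] != self.sites.n_sites:
            raise ValueError("CT coupling block does not match number of sites")

    @property
    def n_sites(self) -> int:
        return self.sites.n_sites

    @property
    def n_ct(self) -> int:
        return 0 if self.ct is None else self.ct.n_ct

    @property
    def dimension(self) -> int:
        return self.n_sites + self.n_ct

    def matrix(self) -> np.ndarray:
        """Dense real-symmetric matrix representation (cm^-1)."""
        n_p, n_ct = self.n_sites, self.n_ct
        h = np.zeros((n_p + n_ct, n_p + n_ct))
        h[:n_p, :n_p] = self.couplings.values
        h[np.arange(n_p), np.arange(n_p)] = self.sites.site_energies
        if self.ct is not None:
            h[n_p:, n_p:] = np.diag(self.ct.ct_energies)
            h[:n_p, n_p:] = self.ct.ct_couplings
            h[n_p:, :n_p] = self.ct.ct_couplings.T
        return h


@dataclass
class ExcitonState:
    """One eigenstate of the (augmented) exciton Hamiltonian."""

    energy: float
    coefficients: np.ndarray  # over sites then CT states, unit norm
    n_sites: int
    transition_dipole: np.ndarray | None = None  # Debye
    dipole_strength: float | None = None  # Debye^2
    rotational_strength: float | None = None  # model units (spectra are normalized)
    k_label: int | str | None = None

    @property
    def site_coefficients(self) -> np.ndarray:
        return self.coefficients[: self.n_sites]

    @property
    def ct_coefficients(self) -> np.ndarray:
        return self.coefficients[self.n_sites :]

    @property
    def qy_weight(self) -> float:
        return float(np.sum(self.site_coefficients**2))

    @property
    def ipr(self) -> float:
        """Inverse participation ratio 1 / sum_i c_i^4."""
        return float(1.0 / np.sum(self.coefficients**4))

    @property
    def site_participation(self) -> float:
        """sum_i c_i^4 over Qy sites — the exchange-narrowing factor of the state."""
        return float(np.sum(self.site_coefficients**4))


def assemble_hamiltonian(
    sites: SiteBasis,
    couplings: CouplingMatrix,
    ct: CTManifold | None = None,
) -> AugmentedHamiltonian:
    """Assemble the (CT-augmented) exciton Hamiltonian; validation happens in
    the dataclass constructors."""
    return AugmentedHamiltonian(sites=sites, couplings=couplings, ct=ct)


def _fix_gauge(vecs: np.ndarray) -> np.ndarray:
    """Deterministic sign gauge: first coefficient with |c| > 1e-8 is positive."""
    out = vecs.copy()
    for k in range(out.shape[1]):
        col = out[:, k]
        idx = np.nonzero(np.abs(col) > 1e-8)[0]
        if idx.size and col[idx[0]] < 0:
            out[:, k] = -col
    return out


def diagonalize(h: AugmentedHamiltonian) -> list[ExcitonState]:
    """Eigenstates in ascending energy order with a deterministic sign gauge."""
    m = h.matrix()
    if not np.all(np.isfinite(m)):
        raise ValueError("Hamiltonian contains non-finite entries")
    evals, evecs = scipy.linalg.eigh(m)
    evecs = _fix_gauge(evecs)
    return [
        ExcitonState(energy=float(evals[k]), coefficients=evecs[:, k], n_sites=h.n_sites)
        for k in range(m.shape[0])
    ]


def state_dipoles(
    states: Sequence[ExcitonState], geometry: RingGeometry
) -> list[ExcitonState]:
    """Attach transition dipole vectors mu_k = sum_i c_ki mu_i and dipole
    strengths |mu_k|^2; CT coefficients contribute no dipole."""
    mus = geometry.dipoles
    if mus.shape[0] != states[0].n_sites:
        raise ValueError(
            f"geometry has {mus.shape[0]} pigments but states have "
            f"{states[0].n_sites} Qy sites"
        )
    for s in states:
        mu = s.site_coefficients @ mus
        s.transition_dipole = mu
        s.dipole_strength = float(mu @ mu)
    return list(states)


def rotational_strengths(
    states: Sequence[ExcitonState], geometry: RingGeometry
) -> list[ExcitonState]:
    """Exciton rotational strengths for circular dichroism.

    R_k = nu_k * sum_{i<j} c_ki c_kj (r_i - r_j) . (mu_i x mu_j), in model
    units (positions in Angstrom, dipoles in Debye, nu in cm^-1); CD spectra
    built from these are max-normalized, so only relative values matter.
    The conservativity sum rule sum_k R_k / nu_k = 0 follows from eigenvector
    orthonormality.
    """
    mus = geometry.dipoles
    centers = geometry.centers
    if mus.shape[0] != states[0].n_sites:
        raise ValueError("geometry/site count mismatch")
    # precompute antisymmetric pair factor G_ij = (r_i - r_j) . (mu_i x mu_j)
    cross = np.cross(mus[:, None, :], mus[None, :, :])
    dr = centers[:, None, :] - centers[None, :, :]
    g = np.einsum("ijk,ijk->ij", dr, cross)
    for s in states:
        c = s.site_coefficients
        # sum over i<j of c_i c_j G_ij; G is symmetric under i<->j exchange
        # ((r_i-r_j) and (mu_i x mu_j) both flip sign), so halve the full sum
        s.rotational_strength = float(0.5 * s.energy * (c @ g @ c))
    return list(states)


def k_labels(
    states: Sequence[ExcitonState],
    symmetry_order: int,
    pigments_per_unit: int | None = None,
    dominance: float = 0.6,
) -> list[ExcitonState]:
    """Assign ring quantum numbers |k| by discrete Fourier analysis.

    The Qy coefficients of each state are reshaped to (units, pigments/unit)
    and Fourier transformed along the unit index; spectral power at +k and -k
    is folded.  The label is the dominant |k| in 0..n//2, or ``"mixed"`` when
    its share of the total power is below ``dominance`` (disorder-localized
    states).  Nonzero |k| labels the doubly degenerate pair of an ideal ring.
    """
    n = symmetry_order
    n_p = states[0].n_sites
    if n_p % n != 0:
        raise ValueError(f"symmetry order {n} does not divide {n_p} sites")
    ppu = n_p // n
    if pigments_per_unit and pigments_per_unit != ppu:
        raise ValueError("pigments_per_unit inconsistent with site count")
    for s in states:
        c = s.site_coefficients.reshape(n, ppu)
        power = np.abs(np.fft.fft(c, axis=0)) ** 2  # (n, ppu)
        power = power.sum(axis=1)
        total = power.sum()
        if total == 0:
            s.k_label = "mixed"
            continue
        folded = np.zeros(n // 2 + 1)
        for k in range(n):
            folded[min(k, n - k)] += power[k]
        best = int(np.argmax(folded))
        s.k_label = best if folded[best] / total >= dominance else "mixed"
    return list(states)


def band_summary(states: Sequence[ExcitonState], qy_threshold: float = 0.5) -> dict:
    """Summary of the exciton band.

    bright_energy: dipole-strength-weighted mean energy of the two states with
    the largest dipole strengths (for an ideal ring these are the degenerate
    k = +/-1 pair, which carries nearly all the intensity).
    band_width: max - min energy over Qy-dominated states (Qy weight above
    ``qy_threshold``, which excludes CT-dominated states).
    ipr: per-state inverse participation ratios in state order.
    """
    if not states:
        raise ValueError("no states given")
    qy_states = [s for s in states if s.qy_weight >= qy_threshold] or list(states)
    energies = np.array([s.energy for s in qy_states])
    summary = {
        "band_width": float(energies.max() - energies.min()),
        "ipr": np.array([s.ipr for s in states]),
    }
    with_dipoles = [s for s in qy_states if s.dipole_strength is not None]
    if len(with_dipoles) >= 2:
        top = sorted(with_dipoles, key=lambda s: -s.dipole_strength)[:2]
        weights = np.array([s.dipole_strength for s in top])
        if weights.sum() > 0:
            summary["bright_energy"] = float(
                np.average([s.energy for s in top], weights=weights)
            )
        else:
            summary["bright_energy"] = float(np.mean([s.energy for s in top]))
    elif with_dipoles:
        summary["bright_energy"] = with_dipoles[0].energy
    return summary


def circulant_eigenvalues(eps: float, v: float, n: int) -> np.ndarray:
    """Closed-form spectrum eps + 2 V cos(2 pi k / n) of a homogeneous
    nearest-neighbor ring, ascending; the analytic oracle for ring numerics."""
    k = np.arange(n)
    return np.sort(eps + 2.0 * v * np.cos(2.0 * np.pi * k / n))


# ---------------------------------------------------------------------------
# Plain-text round trip


def write_hamiltonian(h: AugmentedHamiltonian, path) -> None:
    """Serialize to a whitespace-separated text format with a small header."""
    lines = [
        f"# n_sites {h.n_sites}",
        f"# n_ct {h.n_ct}",
        "# classes " + " ".join(h.sites.classes),
    ]
    if h.ct is not None:
        pairs = " ".join(f"{i},{j}" for i, j in h.ct.adjacency)
        lines.append(f"# ct_pairs {pairs}")
    for row in h.matrix():
        lines.append(" ".join(f"{x:.10g}" for x in row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_hamiltonian(path) -> AugmentedHamiltonian:
    header: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, rest = line[1:].strip().partition(" ")
                header[key] = rest
            else:
                rows.append([float(x) for x in line.split()])
    m = np.array(rows)
    n_p = int(header["n_sites"])
    n_ct = int(header.get("n_ct", 0))
    classes = tuple(header.get("classes", "").split()) or ("Qy",) * n_p
    sites = SiteBasis(site_energies=np.diag(m)[:n_p], classes=classes)
    coup = m[:n_p, :n_p].copy()
    np.fill_diagonal(coup, 0.0)
    ct = None
    if n_ct:
        pairs = tuple(
            tuple(int(x) for x in p.split(",")) for p in header["ct_pairs"].split()
        )
        ct = CTManifold(
            ct_energies=np.diag(m)[n_p:],
            ct_couplings=m[:n_p, n_p:],
            adjacency=pairs,
        )
    return AugmentedHamiltonian(sites=sites, couplings=CouplingMatrix(coup), ct=ct)


def write_states_table(states: Sequence[ExcitonState], path) -> None:
    """Tabular per-state output: energy, dipole strength, R, k label, IPR."""
    df = pd.DataFrame(
        {
            "energy_cm1": [s.energy for s in states],
            "dipole_strength_D2": [s.dipole_strength for s in states],
            "rotational_strength": [s.rotational_strength for s in states],
            "k_label": [s.k_label for s in states],
            "ipr": [s.ipr for s in states],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
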