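"""Whole-complex analyses: average Hamiltonians from parameter bundles,
ensemble-averaged spectra, mixed-model decomposition and the CT effect.

A :class:`ParameterBundle` captures the excitonic parameters of one LH2
complex — per-class Qy site energies, the named couplings of the two-ring
topology, the ring symmetry order, and optionally the CT-state parameters of
the strongly coupled alpha/beta (B850) ring.  The two packaged bundles
describe the heptameric LH2 of *Mch. purpuratum* (LH2purp, 14 B850 + 7 B800
BChls) and the nonameric LH2 of *Rbl. acidophilus* (LH2acid, 18 + 9).

The mixed-model analysis decomposes the difference between the bright
k = +/-1 exciton energies of two complexes by substituting one parameter set
(site energies, couplings, or both) of the base complex with the other's,
using disorder-free average Hamiltonians.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .disorder import DisorderModel, HamiltonianEnsemble, synthesize_md_like_ensemble
from .exciton import (
    AugmentedHamiltonian,
    CouplingMatrix,
    CTManifold,
    SiteBasis,
    band_summary,
    diagonalize,
    k_labels,
    rotational_strengths,
    state_dipoles,
)
from .geometry import PigmentSpec, RingGeometry, build_ideal_ring
from .lineshape import (
    LineshapeFunction,
    SpectralDensity,
    homogeneous_absorption,
    homogeneous_cd,
    lineshape_g,
)

__all__ = [
    "ParameterBundle",
    "SpectrumResult",
    "bundle_geometry",
    "average_hamiltonian",
    "bright_state_energy",
    "mixed_model_shift",
    "ensemble_spectra",
    "peak_positions",
    "ct_effect",
    "b800_splitting",
    "DEFAULT_BAND_WINDOWS",
]

COUPLING_KEYS = (
    "intra_dimer",
    "inter_dimer",
    "alpha_alpha",
    "beta_beta",
    "b800_b800",
    "inter_ring",
)

#: Band windows on the unshifted (computed) energy axis, cm^-1.  They bracket
#: the B850 bright states (~12900-13300) and the B800 band (~13550-13800) of
#: the packaged average Hamiltonians, with room for CT-induced red shifts and
#: disorder tails; configurable per run.
DEFAULT_BAND_WINDOWS = {"B850": (12000.0, 13400.0), "B800": (13400.0, 14250.0)}


@dataclass(frozen=True)
class ParameterBundle:
    """Excitonic parameters of one LH2 complex.

    ``site_energies`` maps the three BChl classes (alpha, beta, B800) to Qy
    energies in cm^-1; ``couplings`` holds the named couplings of the ring
    topology in cm^-1; ``ct`` (optional) holds ``energy``, ``intra_coupling``
    and ``inter_coupling`` for the CT states of adjacent alpha-beta pairs.
    ``provenance`` flags each parameter key as measured input or package
    default, and is surfaced in run manifests.
    """

    name: str
    site_energies: Mapping[str, float]
    couplings: Mapping[str, float]
    n_units: int
    ct: Mapping[str, float] | None = None
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [k for k in ("alpha", "beta", "B800") if k not in self.site_energies]
        if missing:
            raise ValueError(f"bundle {self.name!r} missing site energies: {missing}")
        missing = [k for k in COUPLING_KEYS if k not in self.couplings]
        if missing:
            raise ValueError(f"bundle {self.name!r} missing couplings: {missing}")
        if self.n_units < 2:
            raise ValueError("n_units must be >= 2")

    def replace(self, **kwargs) -> "ParameterBundle":
        data = {
            "name": self.name,
            "site_energies": dict(self.site_energies),
            "couplings": dict(self.couplings),
            "n_units": self.n_units,
            "ct": dict(self.ct) if self.ct else None,
            "provenance": dict(self.provenance),
        }
        data.update(kwargs)
        return ParameterBundle(**data)


def bundle_geometry(
    bundle: ParameterBundle,
    nn_distance: float = 9.2,
    b800_radial_offset: float = 5.0,
    b800_axial_offset: float = -16.5,
    dipole_magnitude: float = 6.3,
    dipole_tilt: float = 0.15,
) -> RingGeometry:
    """Idealized Cn geometry of the two concentric BChl rings.

    The B850 radius is set so that nearest neighbors in the 2n-membered
    alpha/beta ring sit ``nn_distance`` apart (Mg-Mg ~9 A in LH2 structures);
    alpha and beta Qy dipoles are tangential and antiparallel with a small
    alternating out-of-plane tilt (radians), which is what makes the exciton
    CD couplet non-vanishing.  B800 pigments sit on a wider, axially offset
    ring with in-plane dipoles.
    """
    n = bundle.n_units
    radius = nn_distance / (2.0 * np.sin(np.pi / (2 * n)))
    half = np.pi / (2 * n)  # half the alpha-beta spacing: uniform 2n ring
    spec = [
        PigmentSpec(
            angular_offset=-half,
            dipole_polar=np.pi / 2 + dipole_tilt,
            dipole_azimuth=np.pi / 2,
            dipole_magnitude=dipole_magnitude,
            label="alpha",
        ),
        PigmentSpec(
            angular_offset=+half,
            dipole_polar=np.pi / 2 - dipole_tilt,
            dipole_azimuth=-np.pi / 2,
            dipole_magnitude=dipole_magnitude,
            label="beta",
        ),
        PigmentSpec(
            radial_offset=b800_radial_offset,
            axial_offset=b800_axial_offset,
            dipole_polar=np.pi / 2,
            dipole_azimuth=np.pi / 3,
            dipole_magnitude=dipole_magnitude,
            label="B800",
        ),
    ]
    return build_ideal_ring(n, spec, radius)


def _site_indices(n_units: int) -> tuple[list[int], list[int], list[int]]:
    """Indices of alpha, beta and B800 sites in the interleaved unit order."""
    alphas = [3 * u for u in range(n_units)]
    betas = [3 * u + 1 for u in range(n_units)]
    b800s = [3 * u + 2 for u in range(n_units)]
    return alphas, betas, b800s


def _coupling_matrix(bundle: ParameterBundle) -> np.ndarray:
    n = bundle.n_units
    n_p = 3 * n
    v = np.zeros((n_p, n_p))
    c = bundle.couplings
    alphas, betas, b800s = _site_indices(n)

    def put(i: int, j: int, val: float) -> None:
        v[i, j] = v[j, i] = val

    for u in range(n):
        nxt = (u + 1) % n
        put(alphas[u], betas[u], c["intra_dimer"])
        put(betas[u], alphas[nxt], c["inter_dimer"])
        put(alphas[u], alphas[nxt], c["alpha_alpha"])
        put(betas[u], betas[nxt], c["beta_beta"])
        put(b800s[u], b800s[nxt], c["b800_b800"])
        # inter-ring convention: each B800 couples to the two B850 BChls of
        # its own repeating unit
        put(b800s[u], alphas[u], c["inter_ring"])
        put(b800s[u], betas[u], c["inter_ring"])
    return v


def _ct_manifold(bundle: ParameterBundle, ct_params: Mapping[str, float] | None = None) -> CTManifold:
    """One CT state per adjacent alpha-beta pair of the B850 ring: n intra-
    dimer and n inter-dimer pairs, each coupled to the Qy states of its own
    pair only.

    The two couplings of a pair are given opposite signs, so the CT state
    mixes with the antisymmetric local combination of the pair's Qy states —
    the combination that dominates the low-energy bright k = +/-1 excitons of
    a positively coupled ring.  This is what makes CT mixing red-shift the
    B850 band; the overall per-pair sign is a gauge choice without physical
    consequence.
    """
    params = dict(ct_params or bundle.ct or {})
    for key in ("energy", "intra_coupling", "inter_coupling"):
        if key not in params:
            raise ValueError(f"bundle {bundle.name!r} is missing CT parameter {key!r}")
    n = bundle.n_units
    n_p = 3 * n
    alphas, betas, _ = _site_indices(n)
    pairs: list[tuple[int, int]] = []
    coups: list[tuple[float, float]] = []
    for u in range(n):
        nxt = (u + 1) % n
        pairs.append((alphas[u], betas[u]))
        coups.append((params["intra_coupling"], -params["intra_coupling"]))
        pairs.append((betas[u], alphas[nxt]))
        coups.append((params["inter_coupling"], -params["inter_coupling"]))
    vct = np.zeros((n_p, len(pairs)))
    for m, ((i, j), (vi, vj)) in enumerate(zip(pairs, coups)):
        vct[i, m] = vi
        vct[j, m] = vj
    return CTManifold(
        ct_energies=np.full(len(pairs), params["energy"]),
        ct_couplings=vct,
        adjacency=tuple(pairs),
    )


def average_hamiltonian(
    bundle: ParameterBundle,
    include_ct: bool = False,
    ct_params: Mapping[str, float] | None = None,
) -> AugmentedHamiltonian:
    """Disorder-free Hamiltonian at the bundle's average parameters."""
    n = bundle.n_units
    classes = []
    energies = []
    for _ in range(n):
        for cls in ("alpha", "beta", "B800"):
            classes.append(cls)
            energies.append(bundle.site_energies[cls])
    sites = SiteBasis(site_energies=np.array(energies), classes=tuple(classes))
    coup = CouplingMatrix(_coupling_matrix(bundle))
    ct = _ct_manifold(bundle, ct_params) if include_ct else None
    return AugmentedHamiltonian(sites=sites, couplings=coup, ct=ct)


def bright_state_energy(
    h: AugmentedHamiltonian, geometry: RingGeometry
) -> float:
    """Dipole-strength-weighted mean energy of the two brightest states (the
    k = +/-1 pair of an ideal ring)."""
    states = state_dipoles(diagonalize(h), geometry)
    return band_summary(states)["bright_energy"]


def mixed_model_shift(
    bundle_a: ParameterBundle,
    bundle_b: ParameterBundle,
    mode: str,
) -> float:
    """Bright-state energy change (cm^-1) when substituting parameters of
    ``bundle_a`` with those of ``bundle_b``.

    mode='site' swaps the alpha/beta (B850) site energies, mode='coup' swaps
    all named couplings, mode='site_plus_coup' both, and mode='full' adopts
    the complete bundle_b including its ring size.  For the partial modes the
    substituted values are per-class parameters, so they apply on bundle_a's
    topology even when the two complexes differ in ring size; only
    mode='full' changes the topology itself.  Negative values are red shifts.
    Average (disorder-free) Hamiltonians are used throughout.
    """
    if mode not in ("site", "coup", "site_plus_coup", "full"):
        raise ValueError(f"unknown mode {mode!r}")
    base = bright_state_energy(
        average_hamiltonian(bundle_a), bundle_geometry(bundle_a)
    )
    if mode == "full":
        mixed_bundle = bundle_b
    else:
        site_energies = dict(bundle_a.site_energies)
        couplings = dict(bundle_a.couplings)
        if mode in ("site", "site_plus_coup"):
            site_energies["alpha"] = bundle_b.site_energies["alpha"]
            site_energies["beta"] = bundle_b.site_energies["beta"]
        if mode in ("coup", "site_plus_coup"):
            couplings = dict(bundle_b.couplings)
        mixed_bundle = bundle_a.replace(
            name=f"{bundle_a.name}|{mode}|{bundle_b.name}",
            site_energies=site_energies,
            couplings=couplings,
        )
    mixed = bright_state_energy(
        average_hamiltonian(mixed_bundle), bundle_geometry(mixed_bundle)
    )
    return mixed - base


@dataclass
class SpectrumResult:
    """Ensemble-averaged spectra on a common (optionally shifted) axis."""

    omega: np.ndarray
    absorption: np.ndarray
    cd: np.ndarray
    peaks: dict
    global_shift: float
    provenance: dict = field(default_factory=dict)


def _default_spectral_density() -> SpectralDensity:
    # Drude-Lorentz environment plus a compact set of intramolecular BChl a
    # modes; magnitudes are package defaults chosen to give B850 linewidths
    # of the right order, all overridable through the run configuration.
    return SpectralDensity(
        lambda_env=180.0,
        omega_c=60.0,
        modes=((35.0, 340.0, 20.0), (30.0, 740.0, 20.0), (45.0, 1200.0, 25.0)),
    )


def ensemble_spectra(
    ensemble: HamiltonianEnsemble,
    geometry: RingGeometry,
    spectral_density: SpectralDensity | None = None,
    temperature: float = 300.0,
    global_shift: float = 0.0,
    omega: np.ndarray | None = None,
    t_max: float = 1500.0,
    dt: float = 2.0,
    band_windows: Mapping[str, tuple[float, float]] | None = None,
    normalize: bool = True,
) -> SpectrumResult:
    """Average the homogeneous absorption and CD over all realizations.

    The global shift (e.g. -980 cm^-1 to absorb the systematic error of the
    underlying QM method) is applied once to the output energy axis.  The
    averaged absorption is normalized to its maximum and the CD to its
    largest band, positive or negative.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    sd = spectral_density or _default_spectral_density()
    if omega is None:
        omega = np.arange(11200.0, 14900.0, 2.0)
    omega = np.asarray(omega, dtype=float)
    t = np.arange(0.0, t_max, dt)
    g = lineshape_g(sd, temperature, t)

    absorption = np.zeros(omega.size)
    cd = np.zeros(omega.size)
    with warnings.catch_warnings():
        # one grid-coverage warning per ensemble is enough
        warnings.simplefilter("once")
        for h in ensemble:
            states = diagonalize(h)
            state_dipoles(states, geometry)
            rotational_strengths(states, geometry)
            absorption += homogeneous_absorption(states, g, omega)
            cd += homogeneous_cd(states, g, omega)
    absorption /= len(ensemble)
    cd /= len(ensemble)
    if normalize:
        if absorption.max() > 0:
            absorption = absorption / absorption.max()
        if np.abs(cd).max() > 0:
            cd = cd / np.abs(cd).max()

    shifted = omega + global_shift
    windows = band_windows or DEFAULT_BAND_WINDOWS
    peaks = peak_positions(
        omega, absorption, windows, axis_shift=global_shift
    )
    return SpectrumResult(
        omega=shifted,
        absorption=absorption,
        cd=cd,
        peaks=peaks,
        global_shift=global_shift,
        provenance={
            "n_realizations": len(ensemble),
            "seed": ensemble.seed,
            "temperature_K": temperature,
        },
    )


def peak_positions(
    omega: np.ndarray,
    intensity: np.ndarray,
    band_windows: Mapping[str, tuple[float, float]],
    axis_shift: float = 0.0,
) -> dict:
    """Per-band argmax positions in cm^-1 and nm (nm = 1e7 / cm^-1).

    Windows are given on the unshifted axis; ``axis_shift`` is added to the
    reported positions so they refer to the output (shifted) axis.
    """
    omega = np.asarray(omega, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    out = {}
    for name, (lo, hi) in band_windows.items():
        mask = (omega >= lo) & (omega <= hi)
        if not np.any(mask):
            raise ValueError(f"band window {name!r} [{lo}, {hi}] outside the grid")
        seg = intensity[mask]
        if np.ptp(seg) == 0:
            raise ValueError(f"spectrum is flat within band window {name!r}")
        pos = float(omega[mask][np.argmax(seg)]) + axis_shift
        out[name] = {"cm1": pos, "nm": 1e7 / pos}
    return out


def ct_effect(
    bundle: ParameterBundle,
    model: DisorderModel | None = None,
    n_frames: int = 50,
    seed: int = 0,
    ct_params: Mapping[str, float] | None = None,
    **spectra_kwargs,
) -> dict:
    """Identical spectral pipelines with and without the CT manifold.

    Returns ``{"with_ct", "without_ct", "b850_shift"}`` where the shift is
    the signed B850 peak difference (with - without) in cm^-1; negative
    values mean the CT mixing red-shifts the band.  ``ct_params`` overrides
    the bundle's CT block (useful for comparing CT coupling patterns on a
    common ring).
    """
    if bundle.ct is None and ct_params is None:
        raise ValueError(f"bundle {bundle.name!r} has no CT parameters")
    geometry = bundle_geometry(bundle)
    model = model or DisorderModel(
        sigma_static={"alpha": 60.0, "beta": 60.0, "B800": 60.0}, seed=seed
    )
    base = _coupling_matrix(bundle)
    means = dict(bundle.site_energies)
    common = dict(
        geometry=geometry,
        class_means=means,
        model=model,
        n_frames=n_frames,
        base_couplings=base,
        seed=seed,
    )
    ens_no = synthesize_md_like_ensemble(**common)
    ens_ct = synthesize_md_like_ensemble(
        **common, ct=_ct_manifold(bundle, ct_params)
    )
    res_no = ensemble_spectra(ens_no, geometry, **spectra_kwargs)
    res_ct = ensemble_spectra(ens_ct, geometry, **spectra_kwargs)
    shift = res_ct.peaks["B850"]["cm1"] - res_no.peaks["B850"]["cm1"]
    return {"with_ct": res_ct, "without_ct": res_no, "b850_shift": shift}


def b800_splitting(bundle: ParameterBundle) -> float:
    """Exciton splitting (max - min eigenvalue, cm^-1) of the isolated B800
    ring: a homogeneous n-ring with nearest-neighbor coupling."""
    n = bundle.n_units
    v = np.zeros((n, n))
    for u in range(n):
        v[u, (u + 1) % n] = v[(u + 1) % n, u] = bundle.couplings["b800_b800"]
    h = AugmentedHamiltonian(
        sites=SiteBasis(
            site_energies=np.full(n, bundle.site_energies["B800"]),
            classes=("B800",) * n,
        ),
        couplings=CouplingMatrix(v),
    )
    energies = [s.energy for s in diagonalize(h)]
    return float(max(energies) - min(energies))
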