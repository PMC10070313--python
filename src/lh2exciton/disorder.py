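"""Static disorder models and MD-like Hamiltonian ensembles.

In MD/QM-based exciton simulations of light-harvesting complexes, the slow
(static) part of the site-energy fluctuations is attributed to the protein
environment: the static site energy of frame t is

    E_static = E_env - E_vac + <E_vac>,

where E_env and E_vac are the site energies computed with and without the
environment, and <E_vac> is the vacuum average over all symmetry-equivalent
pigments.  The resulting distribution has the mean of E_env and the standard
deviation of (E_env - E_vac), so intramolecular (fast) fluctuations are
removed from the static distribution and enter only through the homogeneous
lineshape.  On top of the environmental disorder, an additional per-class
Gaussian diagonal disorder broadens each realization, compensating for
disorder sources the MD cannot sample (slow conformational dynamics,
force-field deficiencies).

This module also synthesizes ensembles with the same statistical structure
as per-frame MD/QM output — Gaussian site energies around per-class means,
Gaussian coupling fluctuations around a base coupling matrix — so the full
spectral pipeline can run, and be tested, without any MD input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .exciton import (
    AugmentedHamiltonian,
    CouplingMatrix,
    CTManifold,
    SiteBasis,
    read_hamiltonian,
    write_hamiltonian,
)
from .geometry import RingGeometry, point_dipole_coupling

__all__ = [
    "DisorderRecord",
    "DisorderModel",
    "HamiltonianEnsemble",
    "static_site_energy",
    "sample_realizations",
    "synthesize_md_like_ensemble",
    "estimate_disorder",
    "save_ensemble",
    "load_ensemble",
]


@dataclass(frozen=True)
class DisorderRecord:
    """Per-site environment/vacuum energies of one frame plus per-class
    vacuum averages (cm^-1)."""

    e_env: np.ndarray
    e_vac: np.ndarray
    classes: tuple[str, ...]
    mean_vac: Mapping[str, float]

    def __post_init__(self) -> None:
        env = np.asarray(self.e_env, dtype=float)
        vac = np.asarray(self.e_vac, dtype=float)
        if env.shape != vac.shape:
            raise ValueError("e_env and e_vac must have the same shape")
        if not (np.all(np.isfinite(env)) and np.all(np.isfinite(vac))):
            raise ValueError("energies must be finite")
        if len(self.classes) != env.size:
            raise ValueError("one class per site required")
        object.__setattr__(self, "e_env", env)
        object.__setattr__(self, "e_vac", vac)


@dataclass(frozen=True)
class DisorderModel:
    """Gaussian disorder parameters, all in cm^-1.

    sigma_static: per-class width of the environmental (frame-to-frame) site
    energy distribution.  sigma_add: per-class width of the additional
    diagonal disorder drawn on top of every frame.  sigma_coupling: width of
    the coupling fluctuations used when synthesizing MD-like ensembles.
    correlation: optional site-site correlation matrix for the static draw
    (default: independent sites).
    """

    sigma_static: Mapping[str, float] = field(default_factory=dict)
    sigma_add: Mapping[str, float] = field(default_factory=dict)
    sigma_coupling: float = 0.0
    correlation: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_static", "sigma_add"):
            for cls, s in getattr(self, name).items():
                if s < 0:
                    raise ValueError(f"{name}[{cls!r}] must be >= 0")
        if self.sigma_coupling < 0:
            raise ValueError("sigma_coupling must be >= 0")


@dataclass
class HamiltonianEnsemble:
    """A set of disorder realizations of the exciton Hamiltonian — the
    package's stand-in for per-frame MD/QM Hamiltonians."""

    realizations: list[AugmentedHamiltonian]
    model: DisorderModel | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        dims = {h.dimension for h in self.realizations}
        if len(dims) > 1:
            raise ValueError("all realizations must share dimensions")

    def __len__(self) -> int:
        return len(self.realizations)

    def __iter__(self):
        return iter(self.realizations)

    @property
    def classes(self) -> tuple[str, ...]:
        return self.realizations[0].sites.classes


def static_site_energy(record: DisorderRecord) -> np.ndarray:
    """Static site energies E_env - E_vac + <E_vac> per site (cm^-1).

    Over an ensemble of frames the result keeps the mean of E_env and the
    standard deviation of E_env - E_vac.
    """
    try:
        means = np.array([record.mean_vac[c] for c in record.classes])
    except KeyError as err:
        raise ValueError(f"no vacuum class mean for class {err.args[0]!r}") from None
    return record.e_env - record.e_vac + means


def _class_sigma(sigma: Mapping[str, float], classes: Sequence[str]) -> np.ndarray:
    return np.array([float(sigma.get(c, 0.0)) for c in classes])


def sample_realizations(
    base: HamiltonianEnsemble | AugmentedHamiltonian,
    model: DisorderModel,
    n: int,
    seed: int | None = None,
) -> HamiltonianEnsemble:
    """Draw ``n`` additional-disorder realizations per base Hamiltonian.

    Site energies are perturbed by independent Normal(0, sigma_add(class));
    couplings and CT blocks are left untouched (coupling fluctuations belong
    to the frame ensemble, not the additional disorder).  Fully reproducible
    for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    bases = list(base) if isinstance(base, HamiltonianEnsemble) else [base]
    seed = model.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    out: list[AugmentedHamiltonian] = []
    for h in bases:
        sig = _class_sigma(model.sigma_add, h.sites.classes)
        for _ in range(n):
            delta = rng.normal(0.0, 1.0, size=h.n_sites) * sig
            sites = SiteBasis(
                site_energies=h.sites.site_energies + delta, classes=h.sites.classes
            )
            out.append(AugmentedHamiltonian(sites=sites, couplings=h.couplings, ct=h.ct))
    return HamiltonianEnsemble(realizations=out, model=model, seed=seed)


def synthesize_md_like_ensemble(
    geometry: RingGeometry,
    class_means: Mapping[str, float],
    model: DisorderModel,
    n_frames: int,
    base_couplings: np.ndarray | None = None,
    ct: CTManifold | None = None,
    seed: int | None = None,
) -> HamiltonianEnsemble:
    """Synthesize an ensemble emulating per-frame MD/QM Hamiltonians.

    Per frame, site energies are Normal(class mean, sigma_static(class)) —
    optionally correlated through ``model.correlation`` — and couplings are
    the base couplings plus Normal(0, sigma_coupling) on every off-diagonal
    pair.  The base coupling matrix defaults to vacuum point-dipole couplings
    from the geometry.
    """
    classes = geometry.classes()
    missing = sorted(set(classes) - set(class_means))
    if missing:
        raise ValueError(f"no class mean for class(es) {missing}")
    n_p = len(geometry)
    means = np.array([class_means[c] for c in classes])
    sig = _class_sigma(model.sigma_static, classes)

    if base_couplings is None:
        base_couplings = np.zeros((n_p, n_p))
        for i in range(n_p):
            for j in range(i + 1, n_p):
                v = point_dipole_coupling(geometry.pigments[i], geometry.pigments[j])
                base_couplings[i, j] = base_couplings[j, i] = v
    base_couplings = np.asarray(base_couplings, dtype=float)

    seed = model.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if model.correlation is not None:
        chol = np.linalg.cholesky(np.asarray(model.correlation, dtype=float))
    else:
        chol = None

    iu = np.triu_indices(n_p, k=1)
    out = []
    for _ in range(n_frames):
        z = rng.normal(0.0, 1.0, size=n_p)
        if chol is not None:
            z = chol @ z
        energies = means + sig * z
        coup = base_couplings.copy()
        if model.sigma_coupling > 0:
            dv = rng.normal(0.0, model.sigma_coupling, size=iu[0].size)
            coup[iu] += dv
            coup[(iu[1], iu[0])] += dv
        out.append(
            AugmentedHamiltonian(
                sites=SiteBasis(site_energies=energies, classes=tuple(classes)),
                couplings=CouplingMatrix(coup),
                ct=ct,
            )
        )
    return HamiltonianEnsemble(realizations=out, model=model, seed=seed)


def estimate_disorder(ensemble: HamiltonianEnsemble) -> dict:
    """Unbiased sample statistics of an ensemble, grouped by class and pair.

    Returns ``{"class_mean", "class_sigma", "pair_mean", "pair_sigma"}`` where
    class entries map class label -> cm^-1 (site energies pooled over sites of
    the class and frames) and pair entries map (i, j) -> cm^-1 for every pair
    with a nonzero mean or fluctuating coupling.
    """
    if len(ensemble) < 2:
        raise ValueError("need at least 2 realizations to estimate disorder")
    energies = np.array([h.sites.site_energies for h in ensemble])  # (n, N_p)
    classes = ensemble.classes
    class_mean: dict[str, float] = {}
    class_sigma: dict[str, float] = {}
    for cls in dict.fromkeys(classes):
        cols = [i for i, c in enumerate(classes) if c == cls]
        # pool deviations from each site's own mean so inter-site mean
        # differences do not inflate the width estimate
        block = energies[:, cols]
        class_mean[cls] = float(block.mean())
        dev = block - block.mean(axis=0, keepdims=True)
        class_sigma[cls] = float(
            np.sqrt((dev**2).sum() / (dev.size - len(cols)))
        )
    coups = np.array([h.couplings.values for h in ensemble])
    iu = np.triu_indices(coups.shape[1], k=1)
    pair_mean: dict[tuple[int, int], float] = {}
    pair_sigma: dict[tuple[int, int], float] = {}
    for i, j in zip(*iu):
        series = coups[:, i, j]
        mean = series.mean()
        sd = series.std(ddof=1)
        if abs(mean) > 1e-12 or sd > 1e-12:
            pair_mean[(int(i), int(j))] = float(mean)
            pair_sigma[(int(i), int(j))] = float(sd)
    return {
        "class_mean": class_mean,
        "class_sigma": class_sigma,
        "pair_mean": pair_mean,
        "pair_sigma": pair_sigma,
    }


# ---------------------------------------------------------------------------
# Serialization: directory of matrix files plus a manifest


def save_ensemble(ensemble: HamiltonianEnsemble, directory) -> Path:
    """Write realizations as plain-text matrices plus a YAML manifest from
    which :func:`load_ensemble` restores the ensemble bitwise."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, h in enumerate(ensemble):
        write_hamiltonian(h, directory / f"realization_{i:05d}.txt")
    manifest = {
        "n_realizations": len(ensemble),
        "seed": ensemble.seed,
        "model": _model_to_dict(ensemble.model) if ensemble.model else None,
    }
    path = directory / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return path


def load_ensemble(directory) -> HamiltonianEnsemble:
    directory = Path(directory)
    with open(directory / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    n = manifest["n_realizations"]
    reals = [
        read_hamiltonian(directory / f"realization_{i:05d}.txt") for i in range(n)
    ]
    model = _model_from_dict(manifest.get("model")) if manifest.get("model") else None
    return HamiltonianEnsemble(realizations=reals, model=model, seed=manifest.get("seed"))


def _model_to_dict(model: DisorderModel) -> dict:
    return {
        "sigma_static": dict(model.sigma_static),
        "sigma_add": dict(model.sigma_add),
        "sigma_coupling": float(model.sigma_coupling),
        "seed": int(model.seed),
    }


def _model_from_dict(d: dict) -> DisorderModel:
    return DisorderModel(
        sigma_static=d.get("sigma_static", {}),
        sigma_add=d.get("sigma_add", {}),
        sigma_coupling=d.get("sigma_coupling", 0.0),
        seed=d.get("seed", 0),
    )
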