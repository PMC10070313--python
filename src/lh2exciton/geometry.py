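"""Pigment ring geometry: ideal Cn rings, PDB extraction, and geometric observables.

The geometric quantities computed here are the ones that control excitonic
couplings in antenna rings: center-center distances between bacteriochlorophylls
(BChls), the Förster orientation factor kappa of their Qy transition dipoles,
and hydrogen-bond distances between BChl carbonyl/acetyl oxygens and polar
protein hydrogens.  The BChl center is defined as the midpoint between the NB
and ND nitrogen atoms of the bacteriochlorin macrocycle, and the Qy transition
dipole axis as the normalized NB->ND vector, the standard pseudo-dipole
convention for BChl a.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PigmentGeometry",
    "RingGeometry",
    "PigmentSpec",
    "build_ideal_ring",
    "extract_ring_from_structure",
    "write_ring_pdb",
    "center_distance",
    "orientation_factor",
    "point_dipole_coupling",
    "hbond_distances",
    "hbond_occupancy",
    "write_pair_table",
    "DIPOLE_COUPLING_CONSTANT",
]

#: Vacuum dipole-dipole interaction constant, cm^-1 * Angstrom^3 / Debye^2.
#: V = C * kappa * mu_p * mu_q / R^3.  No environment screening is folded in;
#: screening factors are explicit user multipliers.
DIPOLE_COUPLING_CONSTANT = 5034.1

#: O...H distance below which a hydrogen bond is counted as formed (Angstrom).
#: A summary-statistics convention of this package, not a literature threshold.
HBOND_FORMED_CUTOFF = 2.5


@dataclass(frozen=True)
class PigmentGeometry:
    """A single pigment: label, center (Angstrom), unit dipole axis, magnitude (Debye)."""

    label: str
    center: np.ndarray
    dipole_axis: np.ndarray
    dipole_magnitude: float

    def __post_init__(self) -> None:
        center = np.asarray(self.center, dtype=float)
        axis = np.asarray(self.dipole_axis, dtype=float)
        if center.shape != (3,) or axis.shape != (3,):
            raise ValueError("center and dipole_axis must be 3-vectors")
        if not (np.all(np.isfinite(center)) and np.all(np.isfinite(axis))):
            raise ValueError(f"non-finite coordinates for pigment {self.label!r}")
        norm = np.linalg.norm(axis)
        if norm == 0.0:
            raise ValueError(f"zero-length dipole axis for pigment {self.label!r}")
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "dipole_axis", axis / norm)
        if not np.isfinite(self.dipole_magnitude) or self.dipole_magnitude <= 0:
            raise ValueError(
                f"dipole_magnitude must be positive and finite for pigment {self.label!r}"
            )

    @property
    def dipole(self) -> np.ndarray:
        """Transition dipole vector in Debye."""
        return self.dipole_magnitude * self.dipole_axis

    @property
    def pigment_class(self) -> str:
        """Chain class parsed from the label (text after the last colon),
        e.g. 'alpha', 'beta' or 'B800'."""
        return self.label.split(":")[-1]


@dataclass
class RingGeometry:
    """Ordered pigments of a (possibly idealized) Cn-symmetric ring assembly."""

    pigments: list[PigmentGeometry]
    symmetry_order: int
    pigments_per_unit: int

    def __post_init__(self) -> None:
        if len(self.pigments) != self.symmetry_order * self.pigments_per_unit:
            raise ValueError(
                f"expected {self.symmetry_order * self.pigments_per_unit} pigments, "
                f"got {len(self.pigments)}"
            )

    def __len__(self) -> int:
        return len(self.pigments)

    @property
    def centers(self) -> np.ndarray:
        return np.array([p.center for p in self.pigments])

    @property
    def dipoles(self) -> np.ndarray:
        return np.array([p.dipole for p in self.pigments])

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.pigments]

    def classes(self) -> list[str]:
        return [p.pigment_class for p in self.pigments]


@dataclass(frozen=True)
class PigmentSpec:
    """Placement of one pigment within the repeating unit of an ideal ring.

    Offsets are relative to the unit's reference point on the ring circle;
    dipole orientation is given in the local frame (radial, tangential, axial)
    so that the spec co-rotates with the unit and preserves Cn symmetry.
    ``dipole_polar`` is measured from the ring axis; ``dipole_azimuth`` from
    the outward radial direction towards the tangential direction.
    """

    radial_offset: float = 0.0
    angular_offset: float = 0.0
    axial_offset: float = 0.0
    dipole_polar: float = np.pi / 2
    dipole_azimuth: float = np.pi / 2
    dipole_magnitude: float = 6.3
    label: str = "P"


def build_ideal_ring(
    n_units: int,
    per_unit_spec: Sequence[PigmentSpec],
    radius: float,
) -> RingGeometry:
    """Construct an exactly Cn-symmetric ring of ``n_units`` repeating units.

    The ring axis is z; unit ``u`` is the unit at azimuth ``2*pi*u/n_units``.
    Labels are ``"{u+1}:{spec.label}"`` so that the chain class is recoverable.
    """
    if n_units < 2:
        raise ValueError("n_units must be >= 2")
    if radius <= 0:
        raise ValueError("radius must be positive")
    for spec in per_unit_spec:
        for name in (
            "radial_offset",
            "angular_offset",
            "axial_offset",
            "dipole_polar",
            "dipole_azimuth",
            "dipole_magnitude",
        ):
            if not np.isfinite(getattr(spec, name)):
                raise ValueError(f"non-finite value for PigmentSpec field {name!r}")

    pigments: list[PigmentGeometry] = []
    for u in range(n_units):
        base = 2 * np.pi * u / n_units
        for spec in per_unit_spec:
            theta = base + spec.angular_offset
            r = radius + spec.radial_offset
            radial = np.array([np.cos(theta), np.sin(theta), 0.0])
            tangential = np.array([-np.sin(theta), np.cos(theta), 0.0])
            center = r * radial + np.array([0.0, 0.0, spec.axial_offset])
            axis = (
                np.sin(spec.dipole_polar) * np.cos(spec.dipole_azimuth) * radial
                + np.sin(spec.dipole_polar) * np.sin(spec.dipole_azimuth) * tangential
                + np.cos(spec.dipole_polar) * np.array([0.0, 0.0, 1.0])
            )
            pigments.append(
                PigmentGeometry(
                    label=f"{u + 1}:{spec.label}",
                    center=center,
                    dipole_axis=axis,
                    dipole_magnitude=spec.dipole_magnitude,
                )
            )
    return RingGeometry(
        pigments=pigments,
        symmetry_order=n_units,
        pigments_per_unit=len(per_unit_spec),
    )


# ---------------------------------------------------------------------------
# PDB extraction


def _principal_axis(centers: np.ndarray) -> np.ndarray:
    """Principal axis of the pigment centers (smallest-variance direction is
    perpendicular to the ring plane for a flat ring; we take the eigenvector of
    the covariance with the smallest eigenvalue as the ring axis)."""
    x = centers - centers.mean(axis=0)
    cov = x.T @ x
    w, v = np.linalg.eigh(cov)
    axis = v[:, 0]
    if axis[2] < 0:
        axis = -axis
    return axis


def _order_by_azimuth(
    centers: np.ndarray,
) -> np.ndarray:
    """Indices ordering pigments by azimuth about the principal ring axis,
    ties broken by axial coordinate."""
    axis = _principal_axis(centers)
    origin = centers.mean(axis=0)
    # in-plane basis
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, axis)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = seed - np.dot(seed, axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    rel = centers - origin
    phi = np.arctan2(rel @ e2, rel @ e1)
    # map into [0, 2*pi) with a tolerance well above coordinate-precision
    # noise (PDB rounding moves phi by ~1e-5 rad) but far below any real
    # pigment spacing, so phi = -eps sorts as 0
    tol = 1e-3
    phi = np.where(phi < -tol, phi + 2 * np.pi, np.maximum(phi, 0.0))
    z = rel @ axis
    return np.lexsort((z, np.round(phi, 6)))


def extract_ring_from_structure(
    path,
    residue_names: Sequence[str] = ("BCL", "BCB"),
    atom_nb: str = "NB",
    atom_nd: str = "ND",
    dipole_magnitude: float = 6.3,
    symmetry_order: int | None = None,
    pigments_per_unit: int | None = None,
) -> RingGeometry:
    """Extract pigment centers and Qy dipole axes from a PDB file.

    Centers are NB/ND midpoints, dipole axes normalized NB->ND vectors.
    Both ATOM and HETATM records are accepted; for altloc duplicates the
    highest-occupancy location wins (ties: first encountered).  Pigments are
    ordered by azimuth about the principal axis of their centers.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    atoms = pdb_file.get_structure(model=1, altloc="occupancy")
    mask = np.isin(atoms.res_name, list(residue_names))
    sel = atoms[mask]
    if sel.array_length() == 0:
        raise ValueError(f"no residues named {list(residue_names)} found in {path}")

    pigments = []
    for chain, res_id, res_name in sorted(
        {
            (c, int(r), n)
            for c, r, n in zip(sel.chain_id, sel.res_id, sel.res_name)
        }
    ):
        res = sel[(sel.chain_id == chain) & (sel.res_id == res_id)]
        coords = {}
        for name in (atom_nb, atom_nd):
            hit = res[res.atom_name == name]
            if hit.array_length() == 0:
                raise ValueError(
                    f"residue {res_name} {chain}{res_id} is missing atom {name!r}"
                )
            coords[name] = hit.coord[0]
        nb, nd = coords[atom_nb], coords[atom_nd]
        if np.linalg.norm(nd - nb) == 0:
            raise ValueError(
                f"zero-length {atom_nb}-{atom_nd} vector in residue {res_name} {chain}{res_id}"
            )
        pigments.append(
            PigmentGeometry(
                label=f"{chain}{res_id}:{res_name}",
                center=0.5 * (nb + nd),
                dipole_axis=nd - nb,
                dipole_magnitude=dipole_magnitude,
            )
        )

    centers = np.array([p.center for p in pigments])
    if len(pigments) > 2:
        order = _order_by_azimuth(centers)
        pigments = [pigments[i] for i in order]

    n = symmetry_order or len(pigments)
    ppu = pigments_per_unit or (len(pigments) // n)
    return RingGeometry(pigments=pigments, symmetry_order=n, pigments_per_unit=ppu)


def write_ring_pdb(ring: RingGeometry, path, residue_name: str = "BCL") -> None:
    """Write a minimal PDB with one NB/ND atom pair per pigment.

    The NB/ND pair is placed symmetrically about the pigment center along the
    dipole axis (2.0 A apart, the typical bacteriochlorin NB-ND separation is
    ~4 A but any fixed separation round-trips the center and axis exactly).
    """
    lines = []
    serial = 1
    for i, p in enumerate(ring.pigments, start=1):
        nb = p.center - 1.0 * p.dipole_axis
        nd = p.center + 1.0 * p.dipole_axis
        for name, xyz in (("NB", nb), ("ND", nd)):
            lines.append(
                f"HETATM{serial:>5} {name:<4} {residue_name:>3} A{i:>4}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {name[0]:>2}"
            )
            serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Observables


def center_distance(p: PigmentGeometry, q: PigmentGeometry) -> float:
    """Euclidean center-center distance in Angstrom."""
    return float(np.linalg.norm(p.center - q.center))


def orientation_factor(p: PigmentGeometry, q: PigmentGeometry) -> float:
    """Förster orientation factor kappa = m1.m2 - 3 (m1.r)(m2.r), in [-2, 2]."""
    r = q.center - p.center
    dist = np.linalg.norm(r)
    if dist == 0:
        raise ValueError("orientation factor undefined for coincident centers")
    rhat = r / dist
    m1, m2 = p.dipole_axis, q.dipole_axis
    return float(np.dot(m1, m2) - 3.0 * np.dot(m1, rhat) * np.dot(m2, rhat))


def point_dipole_coupling(
    p: PigmentGeometry,
    q: PigmentGeometry,
    conversion_constant: float = DIPOLE_COUPLING_CONSTANT,
) -> float:
    """Point-dipole excitonic coupling V = C * kappa * mu_p mu_q / R^3 in cm^-1.

    Vacuum interaction; multiply by an explicit screening factor if desired.
    """
    dist = center_distance(p, q)
    if dist == 0:
        raise ValueError("point-dipole coupling undefined for coincident centers")
    kappa = orientation_factor(p, q)
    return (
        conversion_constant
        * kappa
        * p.dipole_magnitude
        * q.dipole_magnitude
        / dist**3
    )


def _resolve_atom(frame: dict, selector) -> np.ndarray:
    if callable(selector):
        hits = [k for k in frame if selector(k)]
    else:
        hits = [k for k in frame if k == selector]
    if len(hits) == 0:
        raise ValueError(f"selector {selector!r} matched no atom")
    if len(hits) > 1:
        raise ValueError(f"selector {selector!r} is ambiguous: matched {hits}")
    return np.asarray(frame[hits[0]], dtype=float)


def hbond_distances(
    frames: Sequence[dict],
    donor_hydrogen,
    acceptor_oxygen,
) -> np.ndarray:
    """Per-frame O...H distance (Angstrom) between a polar hydrogen and a
    BChl oxygen, order preserved.

    Each frame maps atom labels to coordinates; selectors are exact labels or
    predicates on labels and must resolve to exactly one atom per frame.
    """
    out = []
    for frame in frames:
        h = _resolve_atom(frame, donor_hydrogen)
        o = _resolve_atom(frame, acceptor_oxygen)
        out.append(float(np.linalg.norm(o - h)))
    return np.array(out)


def hbond_occupancy(distances: np.ndarray, cutoff: float = HBOND_FORMED_CUTOFF) -> float:
    """Fraction of frames with O...H distance below the formed-bond cutoff."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("no distances given")
    return float(np.mean(d <= cutoff))


def write_pair_table(ring: RingGeometry, path, pairs: Sequence[tuple[int, int]] | None = None) -> None:
    """Write a tab-separated table of pair label, distance (A) and kappa."""
    if pairs is None:
        n = len(ring)
        pairs = [(i, (i + 1) % n) for i in range(n)]
    rows = ["pair\tdistance_A\tkappa"]
    for i, j in pairs:
        p, q = ring.pigments[i], ring.pigments[j]
        rows.append(
            f"{p.label}-{q.label}\t{center_distance(p, q):.4f}\t{orientation_factor(p, q):.6f}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(rows) + "\n")
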