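"""Z-matrix (internal coordinate) representation and Cartesian conversion.

Internal coordinates are the natural frame for averaging flexible molecules:
averaging a bending bond in Cartesian space shortens it, while in internal
coordinates the bond length and the bond angle average independently.

Connectivity is a per-atom reference triplet (bond atom, angle atom, dihedral
atom), each referring to an *earlier* atom; the first three atoms carry
reduced reference sets.  Reconstruction uses the standard natural-extension
(NeRF) placement.  The choice of connectivity matters: defining a ring as one
long chain amplifies angle errors into the implicit closing bond, so chain
definitions are fully overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import MolecularGeometry, wrap_to_pm180

__all__ = [
    "Connectivity",
    "ZMatrix",
    "ZMatrixSeries",
    "NearLinearAngleError",
    "to_internal",
    "to_cartesian",
    "auto_connectivity",
    "chain_connectivity",
]


class NearLinearAngleError(ValueError):
    """Raised when a bond angle sits too close to 0 or 180 degrees to reconstruct."""


@dataclass
class Connectivity:
    """Per-atom Z-matrix references, ``-1`` marking an absent reference."""

    refs: np.ndarray

    def __post_init__(self) -> None:
        self.refs = np.asarray(self.refs, dtype=int)
        if self.refs.ndim != 2 or self.refs.shape[1] != 3:
            raise ValueError("refs must have shape (n_atoms, 3)")
        n = self.refs.shape[0]
        for i in range(n):
            b, a, d = self.refs[i]
            expected_defined = min(i, 3)
            defined = [r for r in (b, a, d) if r >= 0]
            if len(defined) != expected_defined or list(self.refs[i, len(defined):]) != [-1] * (3 - len(defined)):
                raise ValueError(f"atom {i}: expected {expected_defined} references")
            if any(r >= i for r in defined):
                raise ValueError(f"atom {i}: references must point to earlier atoms")
            if len(set(defined)) != len(defined):
                raise ValueError(f"atom {i}: references must be distinct")

    @property
    def n_atoms(self) -> int:
        return self.refs.shape[0]

    def __eq__(self, other) -> bool:
        return isinstance(other, Connectivity) and np.array_equal(self.refs, other.refs)


@dataclass
class ZMatrix:
    """Internal coordinates of one structure (bonds in Angstrom, angles/dihedrals in degrees)."""

    connectivity: Connectivity
    elements: list[str]
    bonds: np.ndarray
    angles: np.ndarray
    dihedrals: np.ndarray

    @property
    def n_atoms(self) -> int:
        return self.connectivity.n_atoms


@dataclass
class ZMatrixSeries:
    """Per-frame internal coordinates under a fixed connectivity.

    Arrays have shape (n_frames, n_atoms); entries for undefined coordinates
    (e.g. the dihedral of atom 2) are NaN.
    """

    connectivity: Connectivity
    elements: list[str]
    bonds: np.ndarray
    angles: np.ndarray
    dihedrals: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.bonds.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.connectivity.n_atoms

    def frame(self, f: int) -> ZMatrix:
        return ZMatrix(self.connectivity, self.elements,
                       self.bonds[f].copy(), self.angles[f].copy(), self.dihedrals[f].copy())


def _angles_deg(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    cosang = np.sum(v1 * v2, axis=-1) / (
        np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1)
    )
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _dihedrals_deg(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral of the chain p0-p1-p2-p3 (IUPAC convention), degrees."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    y = np.sum(np.cross(n1, n2) * (b2 / np.linalg.norm(b2, axis=-1, keepdims=True)), axis=-1)
    x = np.sum(n1 * n2, axis=-1)
    return np.degrees(np.arctan2(y, x))


def to_internal(coords: np.ndarray, connectivity: Connectivity, elements=None):
    """Convert Cartesian coordinates to internal coordinates.

    ``coords`` may be a single (A, 3) structure (returns :class:`ZMatrix`) or
    an (F, A, 3) trajectory (returns :class:`ZMatrixSeries`, vectorized over
    frames).  Dihedrals come out in (-180, 180].
    """
    coords = np.asarray(coords, dtype=float)
    single = coords.ndim == 2
    if single:
        coords = coords[None]
    n_frames, n_atoms = coords.shape[0], coords.shape[1]
    if n_atoms != connectivity.n_atoms:
        raise ValueError("atom count mismatch with connectivity")
    elements = list(elements) if elements is not None else ["X"] * n_atoms
    bonds = np.full((n_frames, n_atoms), np.nan)
    angles = np.full((n_frames, n_atoms), np.nan)
    dihedrals = np.full((n_frames, n_atoms), np.nan)
    refs = connectivity.refs
    for i in range(1, n_atoms):
        b = refs[i, 0]
        bonds[:, i] = np.linalg.norm(coords[:, i] - coords[:, b], axis=-1)
        if i >= 2:
            a = refs[i, 1]
            angles[:, i] = _angles_deg(coords[:, i] - coords[:, b], coords[:, a] - coords[:, b])
        if i >= 3:
            a, d = refs[i, 1], refs[i, 2]
            dihedrals[:, i] = wrap_to_pm180(
                _dihedrals_deg(coords[:, i], coords[:, b], coords[:, a], coords[:, d])
            )
    if single:
        return ZMatrix(connectivity, elements, bonds[0], angles[0], dihedrals[0])
    return ZMatrixSeries(connectivity, elements, bonds, angles, dihedrals)


def _place_nerf(xd, xa, xb, r, theta_deg, phi_deg) -> np.ndarray:
    """Place an atom bonded to ``xb`` with angle at ``xb`` to ``xa`` and dihedral to ``xd``."""
    theta = np.radians(theta_deg)
    phi = np.radians(phi_deg)
    bc = xb - xa
    bc /= np.linalg.norm(bc)
    ab = xa - xd
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise NearLinearAngleError("dihedral reference atoms are collinear")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([
        -r * np.cos(theta),
        r * np.cos(phi) * np.sin(theta),
        r * np.sin(phi) * np.sin(theta),
    ])
    return xb + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def to_cartesian(zmat: ZMatrix, angle_margin_deg: float = 1e-3) -> MolecularGeometry:
    """Reconstruct Cartesian coordinates from a Z-matrix.

    The result reproduces the original geometry up to a rigid motion.  Angles
    within ``angle_margin_deg`` of 0 or 180 degrees make the placement
    ill-conditioned and raise :class:`NearLinearAngleError`.
    """
    refs = zmat.connectivity.refs
    n = zmat.n_atoms
    ang = zmat.angles
    for i in range(2, n):
        if ang[i] < angle_margin_deg or ang[i] > 180.0 - angle_margin_deg:
            raise NearLinearAngleError(f"atom {i}: angle {ang[i]:.6f} deg too close to 0/180")
    coords = np.zeros((n, 3))
    if n >= 2:
        coords[1] = coords[refs[1, 0]] + np.array([zmat.bonds[1], 0.0, 0.0])
    if n >= 3:
        b, a = refs[2, 0], refs[2, 1]
        u = coords[a] - coords[b]
        u /= np.linalg.norm(u)
        helper = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        v = np.cross(helper, u)
        v /= np.linalg.norm(v)
        th = np.radians(ang[2])
        coords[2] = coords[b] + zmat.bonds[2] * (np.cos(th) * u + np.sin(th) * v)
    for i in range(3, n):
        b, a, d = refs[i]
        coords[i] = _place_nerf(coords[d], coords[a], coords[b],
                                zmat.bonds[i], ang[i], zmat.dihedrals[i])
    return MolecularGeometry(list(zmat.elements), coords)


# ---------------------------------------------------------------------------
# connectivity construction

_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "S": 1.05, "P": 1.07, "Cl": 1.02, "Br": 1.20,
}


def chain_connectivity(n_atoms: int) -> Connectivity:
    """Simple chain Z-matrix: atom i refers to atoms i-1, i-2, i-3."""
    refs = np.full((n_atoms, 3), -1, dtype=int)
    for i in range(1, n_atoms):
        refs[i, 0] = i - 1
        if i >= 2:
            refs[i, 1] = i - 2
        if i >= 3:
            refs[i, 2] = i - 3
    return Connectivity(refs)


def auto_connectivity(elements, coords: np.ndarray, scale: float = 1.25) -> Connectivity:
    """Covalent-radius bonding followed by a greedy earlier-atom Z-matrix.

    Atoms keep their input order; each atom bonds to its lowest-index bonded
    earlier neighbour (nearest earlier atom if none), angle/dihedral
    references walk up the already-built tree.  The result is a valid
    connectivity for any geometry, but chain choices (e.g. through a ring)
    can and should be overridden when averaging rings.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    radii = np.array([_COVALENT_RADII.get(e, 0.80) for e in elements])
    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    cutoff = scale * (radii[:, None] + radii[None, :])
    bonded = (dist < cutoff) & ~np.eye(n, dtype=bool)

    refs = np.full((n, 3), -1, dtype=int)

    def _noncollinear(d_idx: int, a_idx: int, b_idx: int) -> bool:
        v1 = coords[a_idx] - coords[d_idx]
        v2 = coords[b_idx] - coords[a_idx]
        cr = np.cross(v1, v2)
        return np.linalg.norm(cr) > 1e-6 * max(np.linalg.norm(v1) * np.linalg.norm(v2), 1e-12)

    for i in range(1, n):
        earlier_bonded = [j for j in range(i) if bonded[i, j]]
        if earlier_bonded:
            b = earlier_bonded[0]
        else:
            b = int(np.argmin(dist[i, :i]))
        refs[i, 0] = b
        if i >= 2:
            cand_a = []
            if refs[b, 0] >= 0:
                cand_a.append(refs[b, 0])
            cand_a += [j for j in range(i) if bonded[b, j] and j != b]
            cand_a += [j for j in range(i) if j != b]
            a = next(j for j in cand_a if j != b and j < i)
            refs[i, 1] = a
        if i >= 3:
            a = refs[i, 1]
            cand_d = []
            if refs[a, 0] >= 0:
                cand_d.append(refs[a, 0])
            if refs[b, 1] >= 0:
                cand_d.append(refs[b, 1])
            cand_d += list(range(i))
            d = next(
                (j for j in cand_d if j < i and j not in (b, a) and _noncollinear(j, a, b)),
                None,
            )
            if d is None:  # pathological (all earlier atoms collinear)
                d = next(j for j in range(i) if j not in (b, a))
            refs[i, 2] = d
    return Connectivity(refs)
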